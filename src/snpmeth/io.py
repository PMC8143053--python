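"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* VCF positions are 1-based; BED intervals are 0-based half-open.  All
  internal coordinates are 1-based inclusive and conversion happens only at
  the file boundary.
* A 1-based position ``p`` lies inside a BED interval ``(start, end)`` iff
  ``start < p <= end``.
* Gene assignment of variants and probes is always taken from the input
  annotations (VCF INFO / probe manifest), never recomputed from coordinates.
* ``.gz`` paths are read and written transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

FUNC_CLASSES = (
    "nonsynonymous_SNV",
    "stopgain",
    "frameshift",
    "splicing",
    "synonymous_SNV",
    "other",
)
SIFT_LABELS = ("damaging", "tolerated", "unknown")

#: columns every variant table carries, in order
VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "gene", "func_class", "sift", "maf"]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class CohortDesign:
    """Case/control assignment of the cohort samples (order preserved)."""

    samples: list[str]
    groups: list[str]  # "case" | "control", parallel to samples

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.groups):
            raise ValueError("samples and groups must have equal length")
        bad = set(self.groups) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def case_samples(self) -> list[str]:
        return [s for s, g in zip(self.samples, self.groups) if g == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in zip(self.samples, self.groups) if g == "control"]

    @property
    def n_case(self) -> int:
        return len(self.case_samples)

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.samples, "group": self.groups})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortDesign":
        return cls(list(df["sample"]), list(df["group"]))


@dataclass
class VariantTable:
    """Annotated variants plus per-sample carrier states.

    ``df`` holds one row per variant (columns :data:`VARIANT_COLUMNS`);
    ``carriers`` is a boolean frame indexed by variant id with one column per
    cohort sample (any non-reference genotype counts as carrier).
    """

    df: pd.DataFrame
    carriers: pd.DataFrame
    n_missing_gt: int = 0

    def __post_init__(self) -> None:
        if list(self.df["id"]) != list(self.carriers.index):
            raise ValueError("carrier matrix index must match variant ids in order")
        if (self.df["maf"] < 0).any() or (self.df["maf"] > 0.5).any():
            raise ValueError("MAF outside [0, 0.5]")

    @property
    def samples(self) -> list[str]:
        return list(self.carriers.columns)

    def subset(self, mask) -> "VariantTable":
        df = self.df.loc[mask].reset_index(drop=True)
        return VariantTable(df, self.carriers.loc[df["id"]], self.n_missing_gt)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got {self.start}..{self.end}")

    def contains_position(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position: start < pos <= end."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass
class IntervalSet:
    """Per-chromosome interval index over a list of :class:`GenomicInterval`."""

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlapping(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """Intervals containing the 1-based position ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        # 1-based pos maps to 0-based coordinate pos-1
        return [hit.data for hit in tree.at(pos - 1)]

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT), with the description field passed through."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Variants (VCF / TSV)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">
##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_variants_vcf(table: VariantTable, path: str | Path) -> None:
    """Write the variant table as VCF v4.2 with GT per sample (0/1 carriers)."""
    with _open_text(path, "wt") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(table.df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        carriers = table.carriers.to_numpy()
        for i, row in enumerate(table.df.itertuples(index=False)):
            info = f"GENE={row.gene};FUNC={row.func_class};SIFT={row.sift};MAF={row.maf:.6g}"
            gts = "\t".join("0/1" if c else "0/0" for c in carriers[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_variants_tsv(table: VariantTable, path: str | Path) -> None:
    """Flat-TSV twin of the VCF: annotation columns then one 0/1 column per sample."""
    flat = table.df.copy()
    flat = pd.concat(
        [flat, table.carriers.astype(int).reset_index(drop=True)], axis=1
    )
    flat.to_csv(path, sep="\t", index=False)


def _read_variants_vcf(path: str | Path) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[dict] = []
    carrier_rows: list[np.ndarray] = []
    n_missing = 0
    for var in vcf:
        info = dict(var.INFO)
        for key in ("GENE", "SIFT", "MAF"):
            if key not in info:
                raise ValueError(
                    f"variant {var.ID or f'{var.CHROM}:{var.POS}'} lacks required INFO field {key}"
                )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        n_missing += int((gt == 2).sum())
        carrier_rows.append((gt == 1) | (gt == 3))
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "gene": info["GENE"],
                "func_class": info.get("FUNC", "other"),
                "sift": info["SIFT"],
                "maf": float(info["MAF"]),
            }
        )
    if n_missing:
        log.info("read_variants: %d missing genotypes treated as non-carrier", n_missing)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    carriers = pd.DataFrame(
        np.vstack(carrier_rows) if carrier_rows else np.empty((0, len(samples)), bool),
        index=df["id"],
        columns=samples,
    )
    return VariantTable(df, carriers, n_missing)


def _read_variants_tsv(path: str | Path) -> VariantTable:
    flat = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in flat.columns]
    if missing:
        raise ValueError(f"variant TSV lacks required columns: {missing}")
    sample_cols = [c for c in flat.columns if c not in VARIANT_COLUMNS]
    df = flat[VARIANT_COLUMNS].copy()
    carriers = flat[sample_cols].astype(bool)
    carriers.index = df["id"]
    return VariantTable(df, carriers)


def read_variants(path: str | Path, dialect: str = "vcf") -> VariantTable:
    """Read variants from VCF v4.2 or the flat TSV dialect.

    Per-sample carrier flags are derived from GT (any non-reference allele);
    missing genotypes (./.) count as non-carrier and are tallied on the
    returned table.
    """
    if dialect == "vcf":
        return _read_variants_vcf(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    raise ValueError(f"unknown variant dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Intervals (BED)
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path) -> IntervalSet:
    """Read a >=3-column BED file into an indexed interval set.

    Overlapping intervals are retained unmerged; ``start >= end`` is a hard
    error naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append(GenomicInterval(chrom, start, end))
    return IntervalSet(intervals)


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Beta matrix + manifest
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta-value matrix (TSV, first column = probe id).

    Validates: rectangular (pandas enforces), no duplicate probe or sample
    ids, every entry within [0, 1].
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids: {dups[:5]}")
    if mat.columns.duplicated().any():
        raise ValueError("duplicate sample ids in matrix header")
    vals = mat.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite beta values in matrix")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("beta values outside [0, 1]")
    return mat


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", index_label="probe")


MANIFEST_COLUMNS = ["probe", "chrom", "pos", "gene", "feature", "island_relation"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise ValueError(f"manifest lacks columns: {missing}")
    if man["probe"].duplicated().any():
        raise ValueError("duplicate probe ids in manifest")
    return man


def write_manifest(man: pd.DataFrame, path: str | Path) -> None:
    man.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read GMT: ``term<TAB>description<TAB>gene1<TAB>gene2...`` (>=3 fields)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need >=3 fields")
            term, desc, genes = fields[0], fields[1], fields[2:]
            sets[term] = frozenset(g for g in genes if g)
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for term, genes in collection.sets.items():
            desc = collection.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Weighted edge list (PPI)
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a TSV edge list (gene_a, gene_b, score in [0,1]).

    Self-edges are dropped with a warning; duplicate undirected edges keep
    the maximum score.
    """
    edges = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    if ((edges["score"] < 0) | (edges["score"] > 1)).any():
        raise ValueError("edge scores outside [0, 1]")
    selfing = edges["gene_a"] == edges["gene_b"]
    if selfing.any():
        log.warning("dropping %d self-edges", int(selfing.sum()))
        edges = edges[~selfing]
    key = edges[["gene_a", "gene_b"]].apply(lambda r: tuple(sorted(r)), axis=1)
    edges = edges.assign(_key=key).sort_values("score").drop_duplicates("_key", keep="last")
    edges[["gene_a", "gene_b"]] = pd.DataFrame(edges["_key"].tolist(), index=edges.index)
    return edges.drop(columns="_key").sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Misc small formats
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line (known disease-gene panel)."""
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g}\n")


MEQTL_COLUMNS = ["chrom", "pos", "gene", "probe", "mode"]


def read_meqtl(path: str | Path) -> pd.DataFrame:
    pairs = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MEQTL_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"meQTL table lacks columns: {missing}")
    bad = set(pairs["mode"]) - {"cis", "trans"}
    if bad:
        raise ValueError(f"unknown meQTL modes: {sorted(bad)}")
    return pairs


def write_meqtl(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
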