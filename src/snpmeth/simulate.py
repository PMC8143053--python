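"""Synthetic case-control cohorts with planted variant/methylation cross-talk.

The generator emulates the study design this pipeline targets: a WES-style
case/control cohort scored as per-gene rare-variant carriers, a small
bimodal beta-value methylation matrix with spiked differential probes, CpG
island intervals placed over a known subset of variant sites, cis/trans
meQTL pairs tying variant loci to probes, and a scale-free protein
interaction graph containing a known disease-gene core.  Every planted
signal is recorded in a :class:`GroundTruth` so downstream stages can be
tested for exact recovery.

All randomness flows from ``params.seed`` through per-stage
``numpy.random.default_rng`` spawns; identical params give byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    CohortDesign,
    GeneSetCollection,
    GenomicInterval,
    VariantTable,
    VARIANT_COLUMNS,
    write_edge_list,
    write_gene_list,
    write_gene_sets,
    write_intervals,
    write_manifest,
    write_matrix,
    write_meqtl,
    write_variants_tsv,
    write_variants_vcf,
)

FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "ExonBnd", "3'UTR", "IGR")
FEATURE_PROBS = (0.12, 0.10, 0.08, 0.06, 0.35, 0.04, 0.05, 0.20)
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
ISLAND_RELATION_PROBS = (0.30, 0.22, 0.13, 0.35)

# genome layout constants: genes tile chr1..chr22 at fixed spacing so that
# islands placed around one variant can never reach another variant
_N_CHROM = 22
_GENE_SPACING = 1_000_000
_VARIANT_SPACING = 10_000
_ISLAND_HALF = 150  # island radius (bp) around a planted variant
_BETA_EDGE = 0.02  # group means kept inside [edge, 1-edge]

# default known disease-gene core for the PPI fixture
DEFAULT_KNOWN_CORE = ("NKX2-5", "GATA4", "TBX5", "NOTCH1", "HAND1", "CITED2")


@dataclass
class SimulationParams:
    """Parameters of one synthetic study; defaults mirror the target design
    (216 cases / 100 controls sequenced, 11 cases / 5 controls on the array).
    """

    seed: int
    n_case: int = 216
    n_control: int = 100
    n_genes: int = 300
    variants_per_gene: tuple[int, int] = (1, 5)
    background_carrier_rate: float = 0.01
    enriched_genes: tuple[tuple[str, float], ...] = ()  # (gene, carrier odds ratio)
    maf_range: tuple[float, float] = (0.0005, 0.049)
    frac_sift_damaging: float = 0.7
    n_probes: int = 3000
    meth_case_n: int = 11
    meth_control_n: int = 5
    beta_modes: tuple[float, float] = (0.25, 0.75)
    beta_dispersion: float = 0.08  # logit-scale SD
    spiked_probes: tuple[tuple[str, float], ...] = ()  # (probe id, signed delta)
    island_coverage: float = 0.2
    n_meqtl_pairs: int = 50
    frac_cis: float = 0.8
    cis_window: int = 1_000_000
    ppi_known_core: tuple[str, ...] = DEFAULT_KNOWN_CORE
    ppi_attach_m: int = 2

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_genes", "n_probes", "meth_case_n", "meth_control_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("background_carrier_rate", "frac_sift_damaging", "island_coverage", "frac_cis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in [0, 0.5], got {self.maf_range}")
        if self.beta_dispersion <= 0:
            raise ValueError("beta_dispersion must be > 0")
        for m in self.beta_modes:
            if not 0.0 < m < 1.0:
                raise ValueError("beta_modes must lie in (0, 1)")
        lo, hi = self.variants_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("variants_per_gene must be a positive range")
        for gene, orr in self.enriched_genes:
            p = self.background_carrier_rate
            if orr <= 0:
                raise ValueError(f"carrier odds ratio for {gene} must be > 0")
            if not 0.0 < p < 1.0:
                raise ValueError(
                    "enriched genes need background_carrier_rate in (0, 1)"
                )
            p_case = orr * p / (1 - p + orr * p)
            if not 0.0 < p_case < 1.0:
                raise ValueError(f"odds ratio {orr} for {gene} pushes carrier probability outside (0,1)")
        for probe, delta in self.spiked_probes:
            if abs(delta) > 1:
                raise ValueError(f"|delta| for {probe} must be <= 1")
            # baseline interval keeping both group means in [edge, 1-edge]
            if abs(delta) >= 1 - 2 * _BETA_EDGE:
                raise ValueError(f"delta {delta} for {probe} leaves no valid baseline mean")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for key in ("variants_per_gene", "maf_range", "beta_modes", "ppi_known_core"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        for key in ("enriched_genes", "spiked_probes"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Record of every planted signal, for recovery testing."""

    enriched_genes: set[str] = field(default_factory=set)
    spiked_probes: dict[str, float] = field(default_factory=dict)
    planted_crosstalk_genes: set[str] = field(default_factory=set)
    island_variants: set[str] = field(default_factory=set)
    meqtl_linked_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.planted_crosstalk_genes <= self.enriched_genes:
            raise ValueError("planted_crosstalk_genes must be a subset of enriched_genes")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "enriched_genes": sorted(self.enriched_genes),
            "spiked_probes": dict(sorted(self.spiked_probes.items())),
            "planted_crosstalk_genes": sorted(self.planted_crosstalk_genes),
            "island_variants": sorted(self.island_variants),
            "meqtl_linked_genes": sorted(self.meqtl_linked_genes),
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            enriched_genes=set(obj["enriched_genes"]),
            spiked_probes={k: float(v) for k, v in obj["spiked_probes"].items()},
            planted_crosstalk_genes=set(obj["planted_crosstalk_genes"]),
            island_variants=set(obj["island_variants"]),
            meqtl_linked_genes=set(obj["meqtl_linked_genes"]),
        )


# ---------------------------------------------------------------------------
# deterministic genome layout shared by all stages
# ---------------------------------------------------------------------------


def gene_names(params: SimulationParams) -> list[str]:
    width = max(4, len(str(params.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, params.n_genes + 1)]


def gene_layout(params: SimulationParams) -> pd.DataFrame:
    """Deterministic gene table: name, chrom, 1-based start (no RNG)."""
    names = gene_names(params)
    chroms = [f"chr{(i % _N_CHROM) + 1}" for i in range(params.n_genes)]
    starts = [((i // _N_CHROM) + 1) * _GENE_SPACING for i in range(params.n_genes)]
    return pd.DataFrame({"gene": names, "chrom": chroms, "start": starts})


def probe_gene(params: SimulationParams, probe_index: int) -> int:
    """Probes cycle through genes: probe i annotates gene i mod n_genes."""
    return probe_index % params.n_genes


def probe_ids(params: SimulationParams) -> list[str]:
    return [f"cg{i:07d}" for i in range(1, params.n_probes + 1)]


def probes_of_gene(params: SimulationParams, gene_index: int) -> list[str]:
    ids = probe_ids(params)
    return [ids[i] for i in range(gene_index, params.n_probes, params.n_genes)]


def _logit(p):
    return np.log(p / (1 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(
    params: SimulationParams,
) -> tuple[VariantTable, CohortDesign, GroundTruth]:
    """Simulate the WES-style cohort.

    Carrier states are Bernoulli(background rate) per variant; for enriched
    genes the carrier odds in cases are multiplied by the stated odds ratio.
    Island membership of variant sites is decided here (probability
    ``island_coverage``, plus the first variant of every enriched gene, which
    anchors the planted cross-talk) and realised later by
    :func:`generate_annotations`.
    """
    rng = np.random.default_rng([1, params.seed])
    layout = gene_layout(params)
    known = {g for g, _ in params.enriched_genes}
    unknown = known - set(layout["gene"])
    if unknown:
        raise ValueError(f"enriched genes not in simulated gene table: {sorted(unknown)}")
    or_by_gene = dict(params.enriched_genes)

    lo, hi = params.variants_per_gene
    n_var_per_gene = rng.integers(lo, hi + 1, size=params.n_genes)
    rows = []
    bases = np.array(list("ACGT"))
    vid = 0
    for g_i, (gene, chrom, start) in enumerate(layout.itertuples(index=False)):
        for k in range(n_var_per_gene[g_i]):
            vid += 1
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                {
                    "id": f"v{vid:06d}",
                    "chrom": chrom,
                    "pos": start + (k + 1) * _VARIANT_SPACING,
                    "ref": bases[ref],
                    "alt": bases[alt],
                    "gene": gene,
                    "func_class": None,
                    "sift": None,
                    "maf": None,
                }
            )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    n_var = len(df)

    df["maf"] = rng.uniform(params.maf_range[0], params.maf_range[1], size=n_var)
    df["sift"] = np.where(
        rng.random(n_var) < params.frac_sift_damaging, "damaging", "tolerated"
    )
    df["func_class"] = rng.choice(
        ["nonsynonymous_SNV", "stopgain", "frameshift", "splicing", "synonymous_SNV"],
        size=n_var,
        p=[0.68, 0.08, 0.07, 0.05, 0.12],
    )
    # planted genes carry their signal by construction: their variants are
    # rare damaging non-synonymous so the qualifying filter cannot erase them
    planted_mask = df["gene"].isin(known).to_numpy()
    df.loc[planted_mask, "sift"] = "damaging"
    df.loc[planted_mask, "func_class"] = "nonsynonymous_SNV"

    p_bg = params.background_carrier_rate
    p_control = np.full(n_var, p_bg)
    p_case = np.array(
        [
            (or_by_gene[g] * p_bg / (1 - p_bg + or_by_gene[g] * p_bg)) if g in or_by_gene else p_bg
            for g in df["gene"]
        ]
    )
    case_carriers = rng.random((n_var, params.n_case)) < p_case[:, None]
    control_carriers = rng.random((n_var, params.n_control)) < p_control[:, None]
    samples = [f"CASE{i:04d}" for i in range(1, params.n_case + 1)] + [
        f"CTRL{i:04d}" for i in range(1, params.n_control + 1)
    ]
    carriers = pd.DataFrame(
        np.hstack([case_carriers, control_carriers]), index=df["id"], columns=samples
    )
    design = CohortDesign(samples, ["case"] * params.n_case + ["control"] * params.n_control)

    island_variants = set(df.loc[rng.random(n_var) < params.island_coverage, "id"])
    # anchor planted cross-talk: the first variant of every enriched gene is
    # guaranteed island-located
    first_variant = df.drop_duplicates("gene").set_index("gene")["id"]
    for gene in known:
        island_variants.add(first_variant[gene])

    truth = GroundTruth(
        enriched_genes=set(known),
        spiked_probes={p: float(d) for p, d in params.spiked_probes},
        planted_crosstalk_genes=set(known),
        island_variants=island_variants,
        meqtl_linked_genes=set(known),
    )
    return VariantTable(df, carriers), design, truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def generate_methylation(
    params: SimulationParams, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, CohortDesign]:
    """Simulate the beta matrix and probe manifest for the array subcohort.

    Baseline probe means come from a two-mode logit-normal mixture; sample
    values are logit-normal around the group mean with logit-scale SD
    ``beta_dispersion``.  Spiked probes shift the case group mean by the
    planted delta; their baseline mean is drawn uniformly from the range
    keeping both group means inside (0, 1), and generation fails if a
    planted delta admits no such baseline.
    """
    if params.beta_dispersion <= 0:
        raise ValueError("beta_dispersion must be > 0")
    rng = np.random.default_rng([2, params.seed])
    ids = probe_ids(params)
    id_to_idx = {p: i for i, p in enumerate(ids)}
    for probe in truth.spiked_probes:
        if probe not in id_to_idx:
            raise ValueError(f"spiked probe {probe} does not exist in the manifest")

    layout = gene_layout(params)
    genes = layout["gene"].to_numpy()
    chroms = layout["chrom"].to_numpy()
    starts = layout["start"].to_numpy()
    gidx = np.arange(params.n_probes) % params.n_genes
    manifest = pd.DataFrame(
        {
            "probe": ids,
            "chrom": chroms[gidx],
            "pos": starts[gidx] + 500 + (np.arange(params.n_probes) // params.n_genes) * 37,
            "gene": genes[gidx],
            "feature": rng.choice(FEATURES, size=params.n_probes, p=FEATURE_PROBS),
            "island_relation": rng.choice(
                ISLAND_RELATIONS, size=params.n_probes, p=ISLAND_RELATION_PROBS
            ),
        }
    )

    mode_pick = rng.random(params.n_probes) < 0.5
    mode = np.where(mode_pick, params.beta_modes[0], params.beta_modes[1])
    base_mean = _invlogit(_logit(mode) + rng.normal(0.0, 0.4, size=params.n_probes))
    base_mean = np.clip(base_mean, _BETA_EDGE, 1 - _BETA_EDGE)

    delta = np.zeros(params.n_probes)
    for probe, d in truth.spiked_probes.items():
        i = id_to_idx[probe]
        lo = max(_BETA_EDGE, _BETA_EDGE - d)
        hi = min(1 - _BETA_EDGE, 1 - _BETA_EDGE - d)
        if lo >= hi:
            raise ValueError(f"delta {d} for probe {probe} leaves no valid baseline mean")
        base_mean[i] = rng.uniform(lo, hi)
        delta[i] = d

    n_case, n_ctrl = params.meth_case_n, params.meth_control_n
    samples = [f"MCASE{i:02d}" for i in range(1, n_case + 1)] + [
        f"MCTRL{i:02d}" for i in range(1, n_ctrl + 1)
    ]
    design = CohortDesign(samples, ["case"] * n_case + ["control"] * n_ctrl)

    mean_mat = np.tile(base_mean[:, None], (1, n_case + n_ctrl))
    mean_mat[:, :n_case] += delta[:, None]
    noise = rng.normal(0.0, params.beta_dispersion, size=mean_mat.shape)
    beta = _invlogit(_logit(mean_mat) + noise)
    matrix = pd.DataFrame(beta, index=pd.Index(ids, name="probe"), columns=samples)
    return matrix, manifest, design


def delta_beta_se(params: SimulationParams, mean: float = 0.5) -> float:
    """Delta-method SE of the case-control sample mean difference for a probe
    with group mean ``mean`` under the logit-normal dispersion model."""
    sd_beta = params.beta_dispersion * mean * (1 - mean)
    return sd_beta * np.sqrt(1 / params.meth_case_n + 1 / params.meth_control_n)


# ---------------------------------------------------------------------------
# annotations: islands, meQTL, gene sets, PPI, known genes
# ---------------------------------------------------------------------------


def generate_annotations(
    params: SimulationParams,
    truth: GroundTruth,
    variants: VariantTable,
    manifest: pd.DataFrame,
) -> dict:
    """Emit islands, meQTL pairs, GMT term sets, PPI edges and the known-gene
    list, consistent with the planted truth.

    Islands are centred on exactly the planted island variants; the fixed
    genome layout guarantees they cannot reach any other variant site, and a
    contradiction check enforces it.  meQTL pairs connect each planted
    gene's anchor variant locus to one of its spiked probes (cis/trans by
    the configured window); background pairs are random variant->probe
    links.  The PPI is a preferential-attachment graph over the simulated
    genes, plus a known-core clique and one high-confidence edge from every
    planted cross-talk gene to a known-core gene.
    """
    rng = np.random.default_rng([3, params.seed])
    df = variants.df.set_index("id")

    # --- islands -----------------------------------------------------------
    islands: list[GenomicInterval] = []
    for vid in sorted(truth.island_variants):
        pos = int(df.loc[vid, "pos"])
        islands.append(GenomicInterval(str(df.loc[vid, "chrom"]), pos - 1 - _ISLAND_HALF, pos + _ISLAND_HALF))
    # contradiction check: no island may cover a non-planted variant
    for iv in islands:
        hits = df[
            (df["chrom"] == iv.chrom) & (df["pos"] > iv.start) & (df["pos"] <= iv.end)
        ].index
        extra = set(hits) - truth.island_variants
        if extra:
            raise ValueError(f"island placement would cover non-planted variants: {sorted(extra)}")

    # --- meQTL pairs -------------------------------------------------------
    man = manifest.set_index("probe")
    layout = gene_layout(params)
    name_to_idx = {g: i for i, g in enumerate(layout["gene"])}
    first_variant = variants.df.drop_duplicates("gene").set_index("gene")

    def _mode(chrom_v, pos_v, probe) -> str:
        chrom_p, pos_p = man.loc[probe, "chrom"], int(man.loc[probe, "pos"])
        if chrom_p == chrom_v and abs(pos_p - pos_v) <= params.cis_window:
            return "cis"
        return "trans"

    pair_rows = []
    spiked_by_gene: dict[str, list[str]] = {}
    for probe in truth.spiked_probes:
        spiked_by_gene.setdefault(str(man.loc[probe, "gene"]), []).append(probe)
    for gene in sorted(truth.planted_crosstalk_genes):
        anchor = first_variant.loc[gene]
        probes = spiked_by_gene.get(gene) or probes_of_gene(params, name_to_idx[gene])[:1]
        probe = sorted(probes)[0]
        pair_rows.append(
            {
                "chrom": anchor["chrom"],
                "pos": int(anchor["pos"]),
                "gene": gene,
                "probe": probe,
                "mode": _mode(anchor["chrom"], int(anchor["pos"]), probe),
            }
        )
    all_probes = list(man.index)
    vdf = variants.df
    for _ in range(params.n_meqtl_pairs):
        row = vdf.iloc[rng.integers(len(vdf))]
        if rng.random() < params.frac_cis:
            # pick a probe on the same chromosome within the window if any
            near = man[(man["chrom"] == row["chrom"]) & (abs(man["pos"] - row["pos"]) <= params.cis_window)]
            probe = near.index[rng.integers(len(near))] if len(near) else all_probes[rng.integers(len(all_probes))]
        else:
            far = man[man["chrom"] != row["chrom"]]
            probe = far.index[rng.integers(len(far))] if len(far) else all_probes[rng.integers(len(all_probes))]
        pair_rows.append(
            {
                "chrom": row["chrom"],
                "pos": int(row["pos"]),
                "gene": row["gene"],
                "probe": probe,
                "mode": _mode(row["chrom"], int(row["pos"]), probe),
            }
        )
    meqtl = pd.DataFrame(pair_rows, columns=["chrom", "pos", "gene", "probe", "mode"])

    # --- term sets (GMT) ---------------------------------------------------
    genes = list(layout["gene"])
    universe = genes + list(params.ppi_known_core)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    namespaces = ["BP", "CC", "MF", "KEGG"]
    for t in range(1, 31):
        size = min(int(rng.integers(10, 51)), len(universe))
        members = rng.choice(len(universe), size=size, replace=False)
        term = f"T{t:03d}"
        sets[term] = frozenset(universe[i] for i in members)
        descriptions[term] = namespaces[t % 4]
    if truth.planted_crosstalk_genes:
        extra = rng.choice(len(genes), size=min(10, len(genes)), replace=False)
        sets["CROSSTALK_SET"] = frozenset(truth.planted_crosstalk_genes) | {
            genes[i] for i in extra
        }
        descriptions["CROSSTALK_SET"] = "BP"
    gene_sets = GeneSetCollection(sets, descriptions)

    # --- PPI ---------------------------------------------------------------
    core = list(params.ppi_known_core)
    ba_seed = int(rng.integers(0, 2**31 - 1))
    ba = nx.barabasi_albert_graph(len(genes), params.ppi_attach_m, seed=ba_seed)
    edge_rows = [
        {"gene_a": genes[u], "gene_b": genes[v], "score": float(rng.uniform(0.4, 0.99))}
        for u, v in ba.edges()
    ]
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            edge_rows.append({"gene_a": core[i], "gene_b": core[j], "score": 0.99})
    for gene in sorted(truth.planted_crosstalk_genes):
        partner = core[rng.integers(len(core))]
        edge_rows.append({"gene_a": gene, "gene_b": partner, "score": 0.95})
    ppi = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "score"])

    return {
        "islands": islands,
        "meqtl": meqtl,
        "gene_sets": gene_sets,
        "ppi_edges": ppi,
        "known_genes": core,
    }


# ---------------------------------------------------------------------------
# scenario helpers + bundle writer
# ---------------------------------------------------------------------------


def crosstalk_scenario(
    seed: int,
    n_planted: int = 10,
    odds_ratio: float = 20.0,
    delta: float = 0.25,
    spikes_per_gene: int = 2,
    **overrides,
) -> SimulationParams:
    """A strong-signal configuration: ``n_planted`` genes each carrier-enriched,
    island-anchored, spiked on the array and wired to the known PPI core.

    Spike signs alternate so hyper- and hypomethylated probes are balanced.
    """
    base = SimulationParams(seed=seed, **overrides)
    names = gene_names(base)
    if n_planted > base.n_genes:
        raise ValueError("more planted genes than simulated genes")
    planted = names[:n_planted]
    spiked = []
    for gi in range(n_planted):
        for k, probe in enumerate(probes_of_gene(base, gi)[:spikes_per_gene]):
            sign = 1 if (gi + k) % 2 == 0 else -1
            spiked.append((probe, sign * delta))
    return SimulationParams(
        seed=seed,
        enriched_genes=tuple((g, odds_ratio) for g in planted),
        spiked_probes=tuple(spiked),
        **overrides,
    )


def generate_bundle(params: SimulationParams, outdir: str | Path) -> GroundTruth:
    """Generate all inputs and write the complete fixture bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants, design, truth = generate_cohort(params)
    matrix, manifest, meth_design = generate_methylation(params, truth)
    ann = generate_annotations(params, truth, variants, manifest)

    write_variants_vcf(variants, outdir / "variants.vcf")
    write_variants_tsv(variants, outdir / "variants.tsv")
    design.to_frame().to_csv(outdir / "design.tsv", sep="\t", index=False)
    write_matrix(matrix, outdir / "beta_matrix.tsv")
    write_manifest(manifest, outdir / "manifest.tsv")
    meth_design.to_frame().to_csv(outdir / "meth_design.tsv", sep="\t", index=False)
    write_intervals(ann["islands"], outdir / "islands.bed")
    write_meqtl(ann["meqtl"], outdir / "meqtl.tsv")
    write_gene_sets(ann["gene_sets"], outdir / "terms.gmt")
    write_edge_list(ann["ppi_edges"], outdir / "ppi.tsv")
    write_gene_list(ann["known_genes"], outdir / "known_genes.txt")
    truth.to_json(outdir / "truth.json")
    (outdir / "params.json").write_text(json.dumps(asdict(params), indent=2, default=list) + "\n")
    return truth
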