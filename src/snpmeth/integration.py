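"""Mutation-methylation cross-talk integration.

Three criteria are applied to the association candidate genes:

1. the gene carries at least one differentially methylated probe (DMS
   overlap), with a hyper/hypo/mixed direction from the probe signs;
2. at least one of the gene's qualifying variants lies inside a CpG
   island interval (1-based position p inside a BED interval iff
   start < p <= end);
3. at least one of the gene's variants matches a meQTL pair — by exact
   locus when the pair carries coordinates, by SNP gene symbol otherwise —
   whose target probe is (by default) a called DMS.

The integration step reports one record per gene in the union with all
flags, plus Venn region counts for the non-empty intersections (optionally
four-way with a known disease-gene set).
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

import pandas as pd

from .io import IntervalSet, VariantTable

log = logging.getLogger(__name__)


def genes_with_dms_overlap(
    candidates: Iterable[str], dms: pd.DataFrame
) -> pd.DataFrame:
    """Candidate genes carrying >=1 DMS probe, with methylation direction.

    ``dms`` must be gene-annotated (the manifest join of
    :func:`snpmeth.methylation.call_dms`).  Direction is hyper/hypo from
    the probe signs, mixed when both occur.
    """
    candidates = set(candidates)
    if dms.empty:
        return pd.DataFrame(columns=["gene", "direction", "probes"])
    rows = []
    for gene, sub in dms.groupby("gene"):
        if gene not in candidates:
            continue
        dirs = set(sub["direction"])
        direction = "mixed" if len(dirs) > 1 else next(iter(dirs))
        rows.append({"gene": gene, "direction": direction, "probes": ",".join(sorted(sub.index))})
    return pd.DataFrame(rows, columns=["gene", "direction", "probes"])


def genes_with_island_variants(
    candidates: Iterable[str], variants: VariantTable, islands: IntervalSet
) -> pd.DataFrame:
    """Candidate genes with >=1 filtered variant inside a CpG island."""
    candidates = set(candidates)
    rows: dict[str, list[str]] = {}
    for row in variants.df.itertuples(index=False):
        if row.gene not in candidates:
            continue
        if islands.overlapping(row.chrom, row.pos):
            rows.setdefault(row.gene, []).append(row.id)
    return pd.DataFrame(
        [{"gene": g, "variants": ",".join(v)} for g, v in sorted(rows.items())],
        columns=["gene", "variants"],
    )


def genes_with_meqtl_links(
    candidates: Iterable[str],
    variants: VariantTable,
    meqtl: pd.DataFrame,
    dms: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    require_dms_target: bool = True,
) -> pd.DataFrame:
    """Candidate genes whose variants match a meQTL pair.

    Matching prefers the exact (chrom, pos) locus; pairs without
    coordinates fall back to the SNP gene symbol (logged downgrade).  With
    ``require_dms_target`` the pair's target probe must be a called DMS.
    Pairs whose probe is absent from the manifest are skipped with a
    warning.
    """
    candidates = set(candidates)
    if require_dms_target and dms is None:
        raise ValueError("require_dms_target needs the DMS table")
    dms_probes = set(dms.index) if dms is not None else set()
    known_probes = set(manifest["probe"]) if manifest is not None else None
    loci = {
        (row.chrom, row.pos): row.gene for row in variants.df.itertuples(index=False)
    }
    cand_loci = {k: g for k, g in loci.items() if g in candidates}
    rows: dict[str, set[str]] = {}
    n_downgraded = 0
    for pair in meqtl.itertuples(index=False):
        if known_probes is not None and pair.probe not in known_probes:
            log.warning("meQTL probe %s absent from manifest; pair skipped", pair.probe)
            continue
        if require_dms_target and pair.probe not in dms_probes:
            continue
        has_locus = pd.notna(pair.chrom) and pd.notna(pair.pos)
        if has_locus:
            gene = cand_loci.get((pair.chrom, int(pair.pos)))
        else:
            gene = pair.gene if pair.gene in candidates else None
            n_downgraded += 1 if gene else 0
        if gene is not None:
            rows.setdefault(gene, set()).add(pair.mode)
    if n_downgraded:
        log.info("meQTL matching: %d pairs matched by gene symbol (no locus)", n_downgraded)
    return pd.DataFrame(
        [{"gene": g, "modes": ",".join(sorted(m))} for g, m in sorted(rows.items())],
        columns=["gene", "modes"],
    )


def venn_counts(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Counts of every non-empty-membership region of the Venn partition.

    Keys name the member sets joined by ``&`` (e.g. ``"dms&island"`` for
    elements in exactly those two sets); counts sum to the union size.
    """
    names = list(sets)
    union = set().union(*sets.values()) if sets else set()
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(union)
            for name in combo:
                inside &= sets[name]
            for name in names:
                if name not in combo:
                    inside -= sets[name]
            counts["&".join(combo)] = len(inside)
    return counts


def integrate(
    dms_genes: pd.DataFrame,
    island_genes: pd.DataFrame,
    meqtl_genes: pd.DataFrame,
    known_genes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Merge the three criterion sets into one record per gene plus Venn
    region counts (four-way when a known-gene set is supplied).
    """
    d_set = set(dms_genes["gene"])
    i_set = set(island_genes["gene"])
    m_set = set(meqtl_genes["gene"])
    direction = dict(zip(dms_genes["gene"], dms_genes["direction"]))
    probes = dict(zip(dms_genes["gene"], dms_genes["probes"]))
    supp_var = dict(zip(island_genes["gene"], island_genes["variants"]))
    modes = dict(zip(meqtl_genes["gene"], meqtl_genes["modes"]))

    union = d_set | i_set | m_set
    rows = []
    for gene in sorted(union):
        rows.append(
            {
                "gene": gene,
                "flag_dms_overlap": gene in d_set,
                "flag_island_variant": gene in i_set,
                "flag_meqtl_link": gene in m_set,
                "direction": direction.get(gene, "none"),
                "meqtl_modes": modes.get(gene, ""),
                "supporting_variants": supp_var.get(gene, ""),
                "supporting_probes": probes.get(gene, ""),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "flag_dms_overlap",
            "flag_island_variant",
            "flag_meqtl_link",
            "direction",
            "meqtl_modes",
            "supporting_variants",
            "supporting_probes",
        ],
    )
    sets: dict[str, set[str]] = {"dms": d_set, "island": i_set, "meqtl": m_set}
    if known_genes is not None:
        sets["known"] = set(known_genes)
    return table, venn_counts(sets)


def case_frequent_genes(
    integrated: pd.DataFrame, burden: pd.DataFrame
) -> pd.DataFrame:
    """Reporting option: integrated genes whose case carrier frequency
    exceeds the control carrier frequency (damage-associated shortlist)."""
    freq = burden.set_index("gene")
    keep = []
    for gene in integrated["gene"]:
        if gene not in freq.index:
            continue
        row = freq.loc[gene]
        if row["case_carriers"] / row["n_case"] > row["control_carriers"] / row["n_control"]:
            keep.append(gene)
    return integrated[integrated["gene"].isin(keep)].reset_index(drop=True)
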