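"""Rare-variant case/control association: filtering, per-variant Fisher scan,
gene-level carrier-collapsing burden test, candidate selection.

The burden test is CMC-style: a sample is a gene carrier iff it carries at
least one qualifying variant in the gene, and the collapsed carrier 2x2
table gets a two-sided Fisher exact test.  The separate per-variant scan
supplies a gene-level Fisher list via the minimum per-variant p, which is
why the two gene lists can differ.  No multiple-testing correction is
applied at this stage; selection uses raw alpha thresholds.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortDesign, VariantTable

log = logging.getLogger(__name__)

#: non-synonymous functional classes kept by the default filter
DAMAGING_CLASSES = frozenset(
    {"nonsynonymous_SNV", "stopgain", "frameshift", "splicing"}
)


def filter_rare_damaging(
    variants: VariantTable,
    maf_max: float = 0.05,
    require_sift_damaging: bool = True,
    classes: Iterable[str] = DAMAGING_CLASSES,
) -> tuple[VariantTable, pd.DataFrame]:
    """Keep rare (MAF strictly below ``maf_max``), SIFT-damaging variants of
    the given functional classes.

    Returns the filtered table plus a per-functional-class count summary of
    the kept variants.
    """
    classes = frozenset(classes)
    df = variants.df
    mask = (df["maf"] < maf_max) & df["func_class"].isin(classes)
    if require_sift_damaging:
        mask &= df["sift"] == "damaging"
    kept = variants.subset(mask.to_numpy())
    if len(kept) == 0:
        log.warning("filter_rare_damaging: no variants pass the filter")
    summary = (
        kept.df.groupby("func_class").size().rename("n_variants").reset_index()
    )
    return kept, summary


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)`` with OR = (a*d)/(b*c); +inf when b*c == 0
    and a*d > 0, NaN (undefined) for the all-zero table, which has p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = np.nan if ad == 0 else np.inf
    else:
        odds = ad / bc
    if a + b + c + d == 0:
        return np.nan, 1.0
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return odds, min(float(p), 1.0)


def variant_fisher_scan(variants: VariantTable, design: CohortDesign) -> pd.DataFrame:
    """Per-variant carrier/non-carrier x case/control Fisher exact scan.

    Output (sorted by p) carries Manhattan-ready columns chrom, pos and
    -log10(p).  Variants absent from every sample are retained with p = 1
    and flagged monomorphic.
    """
    case_cols = design.case_samples
    ctrl_cols = design.control_samples
    carr = variants.carriers
    a = carr[case_cols].sum(axis=1).to_numpy()  # case carriers
    b = carr[ctrl_cols].sum(axis=1).to_numpy()  # control carriers
    c = len(case_cols) - a
    d = len(ctrl_cols) - b
    ors = np.empty(len(a))
    ps = np.empty(len(a))
    for i in range(len(a)):
        ors[i], ps[i] = fisher_exact_2x2(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
    out = variants.df[["id", "chrom", "pos", "gene"]].copy()
    out["case_carriers"] = a
    out["control_carriers"] = b
    out["case_noncarriers"] = c
    out["control_noncarriers"] = d
    out["odds_ratio"] = ors
    out["p"] = ps
    out["neg_log10_p"] = -np.log10(ps)
    out["monomorphic"] = (a + b) == 0
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def gene_burden_test(variants: VariantTable, design: CohortDesign) -> pd.DataFrame:
    """CMC carrier-collapsing burden test per gene.

    A sample is a gene carrier iff it carries >=1 qualifying variant in the
    gene; ``burden_p`` is the Fisher exact p on the collapsed 2x2 and
    ``fisher_min_p`` the minimum per-variant scan p over the gene's
    variants.  Genes with no variants after filtering are absent.
    """
    scan = variant_fisher_scan(variants, design)
    min_p = scan.groupby("gene")["p"].min()
    case_cols = design.case_samples
    ctrl_cols = design.control_samples
    rows = []
    for gene, ids in variants.df.groupby("gene")["id"]:
        gene_carr = variants.carriers.loc[ids].any(axis=0)
        a = int(gene_carr[case_cols].sum())
        b = int(gene_carr[ctrl_cols].sum())
        c = len(case_cols) - a
        d = len(ctrl_cols) - b
        odds, p = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {
                "gene": gene,
                "case_carriers": a,
                "control_carriers": b,
                "n_case": len(case_cols),
                "n_control": len(ctrl_cols),
                "odds_ratio": odds,
                "fisher_min_p": float(min_p[gene]),
                "burden_p": p,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("burden_p", kind="mergesort")
        .reset_index(drop=True)
    )


SELECTION_MODES = ("union", "intersection", "fisher_only", "burden_only")


def select_candidate_genes(
    results: pd.DataFrame,
    fisher_alpha: float = 0.05,
    burden_alpha: float = 0.05,
    mode: str = "union",
    top_alpha: float = 0.01,
) -> pd.DataFrame:
    """Flag genes by the two association routes and select per ``mode``.

    ``fisher_hit``: fisher_min_p < fisher_alpha; ``burden_hit``: burden_p <
    burden_alpha.  The returned frame keeps both flags plus a ``top`` tier
    marking genes significant at ``top_alpha`` on either route.
    """
    if mode not in SELECTION_MODES:
        raise ValueError(f"unknown selection mode {mode!r}; use one of {SELECTION_MODES}")
    if results.empty:
        raise ValueError("empty association results")
    res = results.copy()
    res["fisher_hit"] = res["fisher_min_p"] < fisher_alpha
    res["burden_hit"] = res["burden_p"] < burden_alpha
    res["top"] = (res["fisher_min_p"] < top_alpha) | (res["burden_p"] < top_alpha)
    if mode == "union":
        keep = res["fisher_hit"] | res["burden_hit"]
    elif mode == "intersection":
        keep = res["fisher_hit"] & res["burden_hit"]
    elif mode == "fisher_only":
        keep = res["fisher_hit"]
    else:
        keep = res["burden_hit"]
    return res[keep].reset_index(drop=True)
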