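"""Term over-representation for a gene set against a supplied term->gene map.

The test is the one-sided hypergeometric upper tail P(X >= k) — equivalent
to a one-sided Fisher exact test on the 2x2 membership table — followed by
Benjamini-Hochberg FDR over all tested terms.  The background universe
defaults to the union of all genes in the term map with the queried set's
assayed genes; it is configurable because over-representation p-values
depend strongly on the universe.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

log = logging.getLogger(__name__)


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, ties preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    gene_set: Iterable[str],
    term_map: GeneSetCollection,
    background: Iterable[str] | None = None,
    report_p: float = 0.05,
    report_fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` in every term.

    Genes outside the background are dropped with a warning.  Returns all
    terms sorted by ascending p with columns (term, name, k, K, n, N, p,
    fdr, significant); ``significant`` marks p <= report_p AND
    fdr < report_fdr.
    """
    genes = set(gene_set)
    if background is None:
        bg = set().union(*term_map.sets.values()) | genes
    else:
        bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    dropped = genes - bg
    if dropped:
        log.warning("%d query genes outside the background dropped: %s",
                    len(dropped), sorted(dropped)[:5])
    genes &= bg
    N, n = len(bg), len(genes)
    rows = []
    for term, members in term_map.sets.items():
        members_bg = members & bg
        K = len(members_bg)
        k = len(members_bg & genes)
        # upper tail P(X >= k); k = 0 gives p = 1 exactly
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term": term,
                "name": term_map.descriptions.get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res.assign(fdr=[], significant=[])
    res["fdr"] = bh_fdr(res["p"])
    res["significant"] = (res["p"] <= report_p) & (res["fdr"] < report_fdr)
    return res.sort_values("p", kind="mergesort").reset_index(drop=True)
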