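"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: exact-fraction combinatorics and
O(n*m) / O(n^3) scans, kept free of the package code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    With margins fixed, sums P(table) over all tables whose probability is
    <= that of the observed table, in exact rational arithmetic.
    """
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0:
        return Fraction(1)
    denom = comb(n, c1)
    k_lo = max(0, c1 - (n - r1))
    k_hi = min(r1, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom) for k in range(k_lo, k_hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs)


def iter_all_tables(n_max: int):
    """All 2x2 tables of non-negative integers with total <= n_max."""
    for n in range(n_max + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield a, b, c, n - a - b - c


def hypergeom_upper_tail_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational sum."""
    denom = comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up BH by the textbook recipe: p*m/i then cumulative minimum."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def floyd_warshall_oracle(n_nodes: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """All-pairs unweighted hop distances by Floyd-Warshall."""
    dist = np.full((n_nodes, n_nodes), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in edges:
        dist[u, v] = dist[v, u] = 1.0
    for k in range(n_nodes):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def pearson_sum_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the raw-sum formula, hand-computable on tiny inputs."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return num / den
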