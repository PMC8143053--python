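"""Two-group differential methylation on a beta-value matrix.

The per-probe statistic is an empirical-Bayes moderated t: the pooled
residual variance of each probe is shrunk towards a common prior variance
s0^2 with d0 prior degrees of freedom, both estimated from the ensemble of
probe variances by moment matching on the log scale (digamma/trigamma),
and the test uses a Student t with d0 + d_g degrees of freedom.  The
effect size reported alongside is deltaBeta = mean(case) - mean(control),
computed from plain arithmetic group means with no shrinkage.

A differential methylation site (DMS) is a probe with |deltaBeta| strictly
greater than 0.1 and p strictly below 0.01 (both thresholds configurable);
the direction is hyper when deltaBeta > 0 in cases, hypo otherwise.

Statistics are computed on the beta scale by default; an M-value
(logit-beta) mode is available but the deltaBeta effect size and its
thresholds always stay on the beta scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CohortDesign

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def sample_correlation(
    matrix: pd.DataFrame,
    design: CohortDesign | None = None,
    flag_threshold: float = 0.9,
) -> tuple[pd.DataFrame, list[str]]:
    """Sample x sample Pearson correlation of beta values.

    Zero-variance samples get NaN correlations and are reported as
    undefined rather than propagating silently.  When a design is given,
    samples whose median correlation to their own group falls below
    ``flag_threshold`` are flagged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    vals = matrix.to_numpy(float)
    sd = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
    degenerate = [s for s, z in zip(matrix.columns, sd == 0) if z]
    if degenerate:
        log.warning("zero-variance samples (correlation undefined): %s", degenerate)
    flagged: list[str] = list(degenerate)
    if design is not None:
        groups = dict(zip(design.samples, design.groups))
        for s in matrix.columns:
            mates = [t for t in matrix.columns if t != s and groups.get(t) == groups.get(s)]
            if not mates or s in degenerate:
                continue
            if np.nanmedian(corr.loc[s, mates].to_numpy()) < flag_threshold:
                flagged.append(s)
    return corr, flagged


# ---------------------------------------------------------------------------
# moderated two-group fit
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior
    from observed probe variances ``s2`` with ``df`` residual df each.

    Moment matching on z = log(s2): under the model z has variance
    trigamma(df/2) + trigamma(d0/2); the excess of the empirical variance
    over trigamma(df/2) is inverted through trigamma.  A non-positive
    excess (no evidence of variance heterogeneity) gives d0 = inf with
    s0^2 = the arithmetic mean of the observed variances.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >=2 probes with positive variance to fit the prior")
    if not ok.all():
        log.warning("%d zero-variance probes excluded from prior estimation", int((~ok).sum()))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1))
    resid = evar - float(special.polygamma(1, df / 2))
    if resid > 0:
        d0 = float(2 * _trigamma_inverse(np.array([resid]))[0])
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        d0 = np.inf
        s0_2 = float(s2[ok].mean())  # pooled limit: the common variance estimate
        log.warning("no excess variance dispersion; falling back to d0 = inf pooled limit")
    return d0, s0_2


def fit_two_group_moderated(
    matrix: pd.DataFrame,
    design: CohortDesign,
    d0_override: float | None = None,
    use_m_values: bool = False,
) -> pd.DataFrame:
    """Per-probe moderated two-sample comparison (case minus control).

    Returns a frame indexed by probe with columns mean_diff, s2 (pooled
    residual variance), s2_post (posterior), t_mod, df_total, p, d0, s0_2,
    and zero_variance flag.  ``d0_override`` forces the prior df: 0 gives
    the ordinary pooled t, ``inf`` the fully shrunk limit where every
    denominator uses s0^2.
    """
    case_cols = design.case_samples
    ctrl_cols = design.control_samples
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >=2 samples for a variance estimate")
    vals = matrix.to_numpy(float)
    if use_m_values:
        eps = 1e-6
        vals = np.log2(np.clip(vals, eps, 1 - eps) / (1 - np.clip(vals, eps, 1 - eps)))
        vals_frame = pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)
    else:
        vals_frame = matrix
    x1 = vals_frame[case_cols].to_numpy(float)
    x2 = vals_frame[ctrl_cols].to_numpy(float)
    mean_diff = x1.mean(axis=1) - x2.mean(axis=1)
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (ss1 + ss2) / df_resid

    if d0_override is None:
        d0, s0_2 = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(d0_override)
        if np.isposinf(d0) or d0 > 0:
            _, s0_2 = estimate_variance_prior(s2, df_resid)
        else:
            s0_2 = float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 0.0

    if np.isposinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    # total df is capped at the whole-ensemble residual df, the reference
    # behaviour of the empirical-Bayes moderated t
    df_total = min(df_total, len(s2) * df_resid)

    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, mean_diff / se, np.where(mean_diff == 0, 0.0, np.inf))
    if np.isposinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    zero_var = s2 == 0
    if zero_var.any():
        log.warning("%d probes with zero variance in both groups (t via shrinkage)", int(zero_var.sum()))
    return pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "s2": s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "d0": d0,
            "s0_2": s0_2,
            "zero_variance": zero_var,
        },
        index=matrix.index.rename("probe"),
    )


# ---------------------------------------------------------------------------
# deltaBeta and DMS calling
# ---------------------------------------------------------------------------


def compute_delta_beta(matrix: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    """Group arithmetic means and their exact difference, case minus control."""
    case_cols = design.case_samples
    ctrl_cols = design.control_samples
    if not case_cols or not ctrl_cols:
        raise ValueError("both groups must be non-empty")
    beta_case = matrix[case_cols].mean(axis=1)
    beta_control = matrix[ctrl_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "beta_case": beta_case,
            "beta_control": beta_control,
            "delta_beta": beta_case - beta_control,
        },
        index=matrix.index.rename("probe"),
    )


def probe_stats(
    matrix: pd.DataFrame,
    design: CohortDesign,
    d0_override: float | None = None,
    use_m_values: bool = False,
) -> pd.DataFrame:
    """Full per-probe stats table: deltaBeta + moderated test + BH q-values.

    The q-value column is informational only; DMS calling uses the raw p.
    """
    delta = compute_delta_beta(matrix, design)
    fit = fit_two_group_moderated(matrix, design, d0_override=d0_override, use_m_values=use_m_values)
    stats_df = delta.join(fit[["s2", "s2_post", "t_mod", "df_total", "p", "zero_variance"]])
    stats_df["q"] = multipletests(stats_df["p"].to_numpy(), method="fdr_bh")[1]
    return stats_df


def call_dms(
    stats_df: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    delta_min: float = 0.1,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Call DMS: |delta_beta| > delta_min (strict) AND p < p_max (strict).

    Direction is hyper for positive deltaBeta.  When a manifest is given,
    gene/feature/island_relation annotations are joined on probe id.
    """
    keep = (stats_df["delta_beta"].abs() > delta_min) & (stats_df["p"] < p_max)
    dms = stats_df[keep].copy()
    dms["direction"] = np.where(dms["delta_beta"] > 0, "hyper", "hypo")
    if manifest is not None:
        ann = manifest.set_index("probe")[["gene", "feature", "island_relation"]]
        missing = dms.index.difference(ann.index)
        if len(missing):
            raise KeyError(f"DMS probes missing from manifest: {list(missing[:5])}")
        dms = dms.join(ann)
    n_hyper = int((dms["direction"] == "hyper").sum())
    log.info(
        "DMS: %d total (%d hyper / %d hypo)", len(dms), n_hyper, len(dms) - n_hyper
    )
    return dms


def dms_direction_summary(dms: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of hyper/hypo DMS."""
    counts = dms["direction"].value_counts().reindex(["hyper", "hypo"], fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "direction": counts.index,
            "n": counts.to_numpy(),
            "fraction": counts.to_numpy() / total if total else 0.0,
        }
    )


def region_distribution(
    dms: pd.DataFrame,
    manifest: pd.DataFrame,
    background: pd.Index | None = None,
    enrichment_p: bool = False,
) -> pd.DataFrame:
    """DMS counts/proportions across island_relation x feature (x direction)
    against a background probe set (default: all manifest probes).

    ``ratio`` is the DMS proportion over the background proportion per
    cell.  Optionally adds a per-cell Fisher enrichment p.
    """
    ann = manifest.set_index("probe")
    missing = dms.index.difference(ann.index)
    if len(missing):
        raise KeyError(f"DMS probes missing from manifest: {list(missing[:5])}")
    bg = ann.index if background is None else pd.Index(background)
    bg_tab = (
        ann.loc[bg]
        .groupby(["island_relation", "feature"], observed=False)
        .size()
        .rename("n_background")
    )
    rows = []
    n_dms_total = len(dms)
    n_bg_total = len(bg)
    dms_ann = ann.loc[dms.index][["island_relation", "feature"]].copy()
    dms_ann["direction"] = dms["direction"].to_numpy() if "direction" in dms else "all"
    counts = dms_ann.groupby(["island_relation", "feature", "direction"]).size()
    for (rel, feat), n_bg in bg_tab.items():
        for direction in ("hyper", "hypo", "all"):
            n = int(counts.get((rel, feat, direction), 0))
            if direction == "all" and "direction" in dms:
                n = int(counts.get((rel, feat, "hyper"), 0) + counts.get((rel, feat, "hypo"), 0))
            prop_dms = n / n_dms_total if n_dms_total else 0.0
            prop_bg = n_bg / n_bg_total
            row = {
                "island_relation": rel,
                "feature": feat,
                "direction": direction,
                "n_dms": n,
                "n_background": int(n_bg),
                "prop_dms": prop_dms,
                "prop_background": prop_bg,
                "ratio": (prop_dms / prop_bg) if prop_bg else np.nan,
            }
            if enrichment_p:
                a = n
                b = n_dms_total - n
                c = int(n_bg) - n
                d = n_bg_total - n_dms_total - c
                row["enrich_p"] = stats.fisher_exact([[a, b], [max(c, 0), max(d, 0)]])[1]
            rows.append(row)
    return pd.DataFrame(rows)
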