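"""Per-gene two-group differential expression with optional variance moderation.

The model is the two-group linear model: logFC is the difference of group
means on the log2 scale, tested with a pooled-variance t statistic.  With
``moderate=True`` the per-gene residual variance is shrunk toward a prior
estimated from all genes,

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

and the t statistic gains d0 prior degrees of freedom.  The prior (d0,
s0^2) is estimated by a closed-form method of moments on the observed
variances: under the scaled-inverse-chi-square prior, s^2 / s0^2 follows an
F(d, d0) distribution, whose squared coefficient of variation
``2 (d + d0 - 2) / (d (d0 - 4))`` is matched to the empirical one.  This is
deliberately simpler than the full empirical-Bayes machinery of dedicated
DE packages; the contract is a valid moderated t that converges to the
ordinary pooled t as d0 -> 0.

DEG tables are plain DataFrames indexed by gene with columns
``logFC, t, p_value, q_value, is_deg`` and the compared cohorts stored in
``DataFrame.attrs["comparison"]`` as (group2, group1), logFC = group2 - group1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, cohort_samples

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["logFC", "t", "p_value", "q_value", "is_deg"]


def _moment_match_prior(variances: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments estimate of the prior (d0, s0^2).

    Returns ``d0 = inf`` (complete shrinkage to the common value) when the
    empirical variance of the variances is at or below what d residual df
    alone would produce.
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        return np.inf, float(np.mean(v)) if v.size else 1.0
    m1 = float(np.mean(v))
    c = float(np.var(v, ddof=1)) / m1**2  # squared coefficient of variation
    if c * d <= 2.0:
        return np.inf, m1
    d0 = (4.0 * c * d + 2.0 * d - 4.0) / (c * d - 2.0)
    d0 = float(np.clip(d0, 0.05, 1e8))
    s0_sq = m1 * (d0 - 2.0) / d0 if d0 > 2.0 else m1
    return d0, float(s0_sq)


def fit_gene_stats(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    group2: str,
    group1: str,
    moderate: bool = True,
) -> pd.DataFrame:
    """Fit per-gene two-group statistics (logFC = mean(group2) - mean(group1)).

    Both cohorts need at least two samples.  Returns a DEG table with
    Benjamini-Hochberg q-values and default DEG calls (alpha=0.05,
    lfc_min=0.6); use :func:`call_degs` to re-flag at other thresholds.
    """
    if group2 == group1:
        raise ValueError("comparison groups must be distinct")
    s2 = [s for s in cohort_samples(sheet, group2) if s in expr.values.columns]
    s1 = [s for s in cohort_samples(sheet, group1) if s in expr.values.columns]
    n2, n1 = len(s2), len(s1)
    if n2 < 2 or n1 < 2:
        raise ValueError(
            f"need >=2 samples per cohort, got {group2}:{n2}, {group1}:{n1}"
        )
    d = n1 + n2 - 2
    if d <= 0:
        raise ValueError("zero residual degrees of freedom")

    x2 = expr.values[s2].to_numpy()
    x1 = expr.values[s1].to_numpy()
    mean2, mean1 = x2.mean(axis=1), x1.mean(axis=1)
    logfc = mean2 - mean1
    ss = ((x2 - mean2[:, None]) ** 2).sum(axis=1) + ((x1 - mean1[:, None]) ** 2).sum(axis=1)
    s_sq = ss / d

    if moderate:
        d0, s0_sq = _moment_match_prior(s_sq, d)
        if np.isinf(d0):
            s_tilde_sq = np.full_like(s_sq, s0_sq)
            df = np.inf
        else:
            s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
            df = d + d0
        logger.debug("moderation prior: d0=%.3g s0^2=%.3g", d0, s0_sq)
    else:
        s_tilde_sq = s_sq
        df = d

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (logfc != 0), np.sign(logfc) * np.inf, t)
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p_value": p,
            "q_value": adjust_bh(p),
            "is_deg": False,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    table.attrs["comparison"] = (group2, group1)
    return call_degs(table)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(table: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.6) -> pd.DataFrame:
    """Flag DEGs with the strict rule q < alpha AND |logFC| > lfc_min."""
    out = table.copy()
    out.attrs = dict(table.attrs)
    out["is_deg"] = (out["q_value"] < alpha) & (out["logFC"].abs() > lfc_min)
    n_up = int(((out["is_deg"]) & (out["logFC"] > 0)).sum())
    n_down = int(((out["is_deg"]) & (out["logFC"] < 0)).sum())
    out.attrs["n_up"] = n_up
    out.attrs["n_down"] = n_down
    logger.info("DEG call: %d up, %d down (alpha=%g, lfc_min=%g)", n_up, n_down, alpha, lfc_min)
    return out


def intersect_degs(tables: list[pd.DataFrame], direction_consistent: bool = True) -> list[str]:
    """Genes flagged is_deg in every table, optionally with matching logFC sign."""
    if len(tables) < 2:
        raise ValueError("need at least two DEG tables to intersect")
    common: set[str] | None = None
    for tab in tables:
        degs = set(tab.index[tab["is_deg"]])
        common = degs if common is None else common & degs
    assert common is not None
    if direction_consistent:
        keep = []
        for g in common:
            signs = {np.sign(tab.loc[g, "logFC"]) for tab in tables}
            if len(signs) == 1:
                keep.append(g)
        common = set(keep)
    return sorted(common)


def exclude_condition_degs(common: list[str], exclusion_table: pd.DataFrame) -> list[str]:
    """Drop genes that are DEGs in the exclusion comparison (e.g. mild sepsis)."""
    flagged = set(exclusion_table.index[exclusion_table["is_deg"]])
    return [g for g in common if g not in flagged]
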