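"""Cross-stratum evidence combination and multiplicity control.

Inverse-variance fixed-effect pooling for coefficient estimates, Fisher's
method for (one-sided dispersion-test) p-values, Benjamini-Hochberg step-up
q-values, and the Bonferroni family threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetaResult",
    "ivw_meta",
    "fisher_combine",
    "bh_fdr",
    "bonferroni_threshold",
]


@dataclass
class MetaResult:
    """Pooled result from one meta-analysis."""

    method: str  # "ivw" | "fisher"
    estimate: float | None
    se: float | None
    statistic: float
    df: int | None
    pvalue: float
    n_strata: int


def ivw_meta(inputs: list[tuple[float, float]]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of (estimate, SE) pairs.

    Weights are 1/SE^2; the pooled SE is 1/sqrt(sum of weights) and the
    p-value the two-sided normal tail of pooled/SE.
    """
    if len(inputs) < 2:
        raise ValueError("inverse-variance meta-analysis needs >= 2 strata")
    est = np.array([b for b, _ in inputs], dtype=float)
    se = np.array([s for _, s in inputs], dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / se**2
    pooled = float(np.sum(w * est) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(
        method="ivw",
        estimate=pooled,
        se=pooled_se,
        statistic=z,
        df=None,
        pvalue=max(p, np.finfo(float).tiny),
        n_strata=len(inputs),
    )


def fisher_combine(pvalues: list[float]) -> MetaResult:
    """Fisher's method: -2 sum(ln p) against chi-square with 2k df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; clip zeros upstream")
    x = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    combined = float(stats.chi2.sf(x, df))
    return MetaResult(
        method="fisher",
        estimate=None,
        se=None,
        statistic=x,
        df=df,
        pvalue=max(combined, np.finfo(float).tiny),
        n_strata=p.size,
    )


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; input order preserved
    and ties handled stably.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha/m for a family of m tests."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m
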