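"""Frequentist two-group comparisons: Welch's t, Hedges' g, chi-squared.

All operations accept either raw samples or (n, mean, sd) summaries, because
published demographic tables only print summaries; computing from summaries
and from the underlying raw data agree exactly.

Sign convention: comparisons are ordered (reference, comparison) and
statistics carry the sign of ``mean_comparison - mean_reference``, so a
positive t for heart rate means the comparison group's heart is faster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = ["GroupSummary", "GroupComparison", "welch_t", "hedges_g", "chi_squared_2x2"]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group for one variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_samples(cls, x: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(x, dtype=float)
        return cls(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


GroupLike = Union[GroupSummary, Sequence[float], np.ndarray]


def _as_summary(g: GroupLike) -> GroupSummary:
    return g if isinstance(g, GroupSummary) else GroupSummary.from_samples(g)


@dataclass(frozen=True)
class GroupComparison:
    """Welch t result, optionally with the Hedges g effect size."""

    t: float
    df: float
    p: float
    g: Optional[float] = None
    g_ci: Optional[tuple[float, float]] = None


def welch_t(a: GroupLike, b: GroupLike) -> GroupComparison:
    """Welch's unequal-variance t-test of (reference a, comparison b).

    t = (mean_b - mean_a) / sqrt(sd_a^2/n_a + sd_b^2/n_b) with
    Welch–Satterthwaite degrees of freedom and a two-sided p-value.
    """
    a, b = _as_summary(a), _as_summary(b)
    va = a.sd**2 / a.n
    vb = b.sd**2 / b.n
    if va + vb == 0:
        raise ValueError("both groups have zero variance: t undefined")
    t = (b.mean - a.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return GroupComparison(t=float(t), df=float(df), p=p)


def _g_ci_noncentral_t(
    d: float, n_a: int, n_b: int, correction: float, conf: float
) -> tuple[float, float]:
    """Invert the noncentral-t CDF for a CI on the standardised difference."""
    if d < 0:  # mirror so the interval is exactly antisymmetric in group order
        lo, hi = _g_ci_noncentral_t(-d, n_a, n_b, correction, conf)
        return (-hi, -lo)
    se_factor = np.sqrt(1.0 / n_a + 1.0 / n_b)
    t_obs = d / se_factor
    df = n_a + n_b - 2
    alpha = 1.0 - conf

    def solve(prob: float) -> float:
        # find ncp such that P(T_{df, ncp} <= t_obs) = prob
        lo, hi = t_obs - 50 - 10 * abs(t_obs), t_obs + 50 + 10 * abs(t_obs)
        return brentq(lambda nc: stats.nct.cdf(t_obs, df, nc) - prob, lo, hi, xtol=1e-8)

    try:
        nc_lo = solve(1.0 - alpha / 2.0)
        nc_hi = solve(alpha / 2.0)
    except ValueError:
        # normal-approximation fallback for extreme inputs
        se_d = np.sqrt((n_a + n_b) / (n_a * n_b) + d**2 / (2 * (n_a + n_b)))
        z = stats.norm.ppf(1 - alpha / 2)
        return (correction * (d - z * se_d), correction * (d + z * se_d))
    return (correction * nc_lo * se_factor, correction * nc_hi * se_factor)


def hedges_g(
    a: GroupLike, b: GroupLike, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Hedges' g (small-sample-corrected standardised mean difference).

    Pooled-SD Cohen's d of (reference a, comparison b) times the correction
    J = 1 - 3/(4(n_a+n_b) - 9); the confidence interval comes from inverting
    the noncentral-t distribution (normal approximation as fallback).
    """
    a, b = _as_summary(a), _as_summary(b)
    if a.n + b.n < 4:
        raise ValueError("need n_a + n_b >= 4")
    pooled = np.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero: effect size undefined")
    d = (b.mean - a.mean) / pooled
    correction = 1.0 - 3.0 / (4.0 * (a.n + b.n) - 9.0)
    g = float(d * correction)
    ci = _g_ci_noncentral_t(d, a.n, b.n, correction, conf)
    return g, (float(ci[0]), float(ci[1]))


def chi_squared_2x2(table: Sequence[Sequence[int]], yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence for a 2x2 count table.

    Returns (chi2, df=1, p). Continuity correction off by default
    (``yates=True`` enables it).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero marginal: chi-squared undefined")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=yates)
    return float(chi2), int(df), float(p)
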