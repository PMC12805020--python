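"""Nonparametric trend inference for learning-curve series.

A per-case metric series, ordered by surgical case number, is tested for a
monotonic trend with the Mann–Kendall test; the trend magnitude is the
Theil–Sen (median-of-pairwise-slopes) estimator with Sen's rank-based
confidence interval; the slope is normalized to a percent change per scale
unit by dividing by the series median; Spearman rank correlation measures
how consistently the metric moves with case number; Bonferroni correction
controls the family-wise error over the (instrument x parameter) grid.

All estimators here are implemented directly from their defining sums, not
delegated, so they can be verified against brute-force pair enumeration.

Notation: for observations y_1..y_n, the Mann–Kendall statistic is

    S = sum_{i<j} sgn(y_j - y_i),

with tie-corrected variance

    Var(S) = [ n(n-1)(2n+5) - sum_t t(t-1)(2t+5) ] / 18

summing over groups of tied values of extent t, and a continuity-corrected
normal deviate z = (S -/+ 1)/sqrt(Var S). The normal approximation is used
at every n (with ~100 cases its error is negligible); exact small-n
enumeration exists only as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateInputError, InsufficientDataError, ValidationError

__all__ = [
    "TrendResult",
    "mann_kendall",
    "theil_sen",
    "percent_change",
    "spearman",
    "bonferroni",
]


@dataclass(frozen=True)
class TrendResult:
    """Full trend inference for one (instrument, parameter) series."""

    parameter: str
    instrument: str
    n: int
    S: int
    varS: float
    z: float
    p: float
    p_adj: float
    sen_slope: float
    sen_ci: tuple[float, float]
    pct_change: float
    pct_ci: tuple[float, float]
    spearman_rho: float
    spearman_p: float


def _tie_groups(y: np.ndarray) -> np.ndarray:
    _, counts = np.unique(y, return_counts=True)
    return counts[counts > 1].astype(np.float64)


def mk_variance(y: np.ndarray) -> float:
    """Tie-corrected variance of the Mann–Kendall S statistic."""
    n = len(y)
    t = _tie_groups(np.asarray(y))
    return (n * (n - 1) * (2 * n + 5) - np.sum(t * (t - 1) * (2 * t + 5))) / 18.0


def mann_kendall(y) -> tuple[int, float, float, float]:
    """Mann–Kendall trend test on a series ordered by its abscissa.

    Returns ``(S, varS, z, p)`` with S the pairwise sign sum, varS its
    tie-corrected variance, z the continuity-corrected normal deviate and
    p the two-sided normal tail probability.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 observations are supplied.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 3:
        raise InsufficientDataError(f"Mann–Kendall needs n >= 3, got {n}")
    sgn = np.sign(y[None, :] - y[:, None])  # sgn[i, j] = sgn(y_j - y_i)
    S = int(np.triu(sgn, k=1).sum())
    varS = mk_variance(y)
    if varS == 0.0:  # all values tied
        return S, 0.0, 0.0, 1.0
    if S > 0:
        z = (S - 1) / math.sqrt(varS)
    elif S < 0:
        z = (S + 1) / math.sqrt(varS)
    else:
        z = 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return S, varS, z, p


def pairwise_slopes(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All (y_j - y_i)/(t_j - t_i) over pairs i < j with t_j != t_i."""
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    i, j = np.triu_indices(t.size, k=1)
    dt = t[j] - t[i]
    keep = dt != 0
    return (y[j] - y[i])[keep] / dt[keep]


def _order_stat(sorted_vals: np.ndarray, rank: float) -> float:
    """Value at a (possibly fractional) 1-based rank, linearly interpolated
    between adjacent order statistics and clamped into [1, N]."""
    N = sorted_vals.size
    r = min(max(rank, 1.0), float(N))
    lo = int(math.floor(r)) - 1
    hi = int(math.ceil(r)) - 1
    if lo == hi:
        return float(sorted_vals[lo])
    frac = r - math.floor(r)
    return float(sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac)


def theil_sen(t, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Theil–Sen slope with Sen's rank-based confidence interval.

    The slope is the median of all pairwise slopes; the (1 - alpha) CI
    takes the order statistics at 1-based ranks (N - C)/2 and
    (N + C)/2 + 1 where C = z_{1-alpha/2} * sqrt(Var S), interpolating at
    fractional ranks. Ties in ``t`` are excluded from the slope list;
    Var S is the tie-corrected Mann–Kendall variance of ``y``.

    Returns ``(slope, ci_lower, ci_upper)``.
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.size != y.size:
        raise ValidationError("t and y must have equal length")
    if np.unique(t).size < 2:
        raise DegenerateInputError("all abscissa values are equal")
    slopes = np.sort(pairwise_slopes(t, y))
    N = slopes.size
    slope = float(np.median(slopes))
    C = sps.norm.ppf(1 - alpha / 2.0) * math.sqrt(mk_variance(y))
    lower = _order_stat(slopes, (N - C) / 2.0)
    upper = _order_stat(slopes, (N + C) / 2.0 + 1.0)
    return slope, lower, upper


def percent_change(
    slope: float,
    y,
    scale_factor: float = 1.0,
    ci: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Normalize a slope to percent change per ``scale_factor`` abscissa units.

    pct = 100 * slope * scale_factor / median(y); the same transform is
    applied to both CI bounds (re-ordered if the median is negative).

    Raises
    ------
    DegenerateInputError
        If the series median is zero.
    """
    med = float(np.median(np.asarray(y, dtype=np.float64)))
    if med == 0.0:
        raise DegenerateInputError("series median is zero; percent change undefined")
    factor = 100.0 * scale_factor / med
    pct = slope * factor
    if ci is None:
        return pct, None
    lo, hi = ci[0] * factor, ci[1] * factor
    return pct, (min(lo, hi), max(lo, hi))


def spearman(t, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value.

    Average ranks are assigned to ties; rho is the product-moment
    correlation of the ranks; p is two-sided from Student's t with n - 2
    degrees of freedom (floored at the smallest positive float so a
    perfect correlation reports p > 0).

    Raises
    ------
    InsufficientDataError
        If n < 3.
    DegenerateInputError
        If either variable is constant (zero rank variance).
    """
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = t.size
    if n < 3:
        raise InsufficientDataError(f"Spearman needs n >= 3, got {n}")
    rt = sps.rankdata(t)
    ry = sps.rankdata(y)
    st, sy = rt.std(), ry.std()
    if st == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero rank variance; correlation undefined")
    rho = float(((rt - rt.mean()) * (ry - ry.mean())).mean() / (st * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = np.finfo(float).tiny
    else:
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(min(1.0, 2.0 * sps.t.sf(abs(tstat), df=n - 2)))
    return rho, max(p, np.finfo(float).tiny)


def bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p) elementwise.

    ``m`` defaults to the number of p-values; it must be at least that.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError(
            f"family size m={m} smaller than the number of tests ({p.size})"
        )
    return np.minimum(1.0, m * p)
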