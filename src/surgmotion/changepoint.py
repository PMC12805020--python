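"""Pettitt single change-point detection on per-case metric series.

The Pettitt test locates the split point where the rank distributions
before and after differ most, via the Mann–Whitney-type statistic

    U_t = sum_{i<=t} sum_{j>t} sgn(y_j - y_i),   t = 1..n-1,

taking K = max_t |U_t| and the first t attaining it as the change-point.
The approximate two-sided significance is p = min(1, 2 exp(-6 K^2 /
(n^3 + n^2))). Being rank-based, K is invariant under strictly monotone
transforms of the series.

By convention here, ``tau_index``/``tau_case`` refer to the LAST point of
the pre-change regime (the split is between positions t and t+1); output
headers document this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError

__all__ = ["ChangePointResult", "pettitt_u", "pettitt_test"]

#: Metric series the change-point scan is applied to by default.
DEFAULT_CHANGEPOINT_PARAMS = ("path_length", "avg_angular_change")


@dataclass(frozen=True)
class ChangePointResult:
    """Pettitt change-point for one (instrument, parameter) series."""

    parameter: str
    instrument: str
    n: int
    tau_index: int  # 1-based position of the last pre-change observation
    tau_case: int  # case number at that position
    K: int  # max_t |U_t|
    p: float  # approximate two-sided significance, capped at 1


def pettitt_u(y) -> np.ndarray:
    """The Pettitt U_t series for t = 1..n-1.

    Computed from the cumulative row sums of the n x n sign matrix;
    identical to the direct double sum.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 4:
        raise InsufficientDataError(f"Pettitt test needs n >= 4, got {n}")
    sgn = np.sign(y[None, :] - y[:, None])  # sgn[i, j] = sgn(y_j - y_i)
    # U_t = sum over rows i <= t (0-based i < t) and columns j > t
    csum = np.cumsum(sgn, axis=0)  # csum[t-1, j] = sum_{i<=t} sgn(y_j - y_i)
    U = np.array(
        [csum[t - 1, t:].sum() for t in range(1, n)], dtype=np.int64
    )
    return U


def pettitt_test(y, case_numbers=None) -> ChangePointResult:
    """Locate the single most likely change-point in a series.

    Parameters
    ----------
    y
        Metric values ordered by case number.
    case_numbers
        Case numbers aligned with ``y``; defaults to 1..n.

    Ties in max |U_t| resolve to the earliest index (deterministic,
    favoring early detection).
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    U = pettitt_u(y)
    absU = np.abs(U)
    tau_index = int(np.argmax(absU)) + 1  # first max, 1-based
    K = int(absU[tau_index - 1])
    p = min(1.0, 2.0 * math.exp(-6.0 * K * K / (n ** 3 + n ** 2)))
    if case_numbers is None:
        tau_case = tau_index
    else:
        case_numbers = np.asarray(case_numbers)
        if case_numbers.size != n:
            raise InsufficientDataError("case_numbers must align with y")
        tau_case = int(case_numbers[tau_index - 1])
    return ChangePointResult(
        parameter="", instrument="", n=n,
        tau_index=tau_index, tau_case=tau_case, K=K, p=p,
    )
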