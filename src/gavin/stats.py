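"""Statistical primitives used by the calibration: type-7 percentiles and
the Mann–Whitney U rank test.

The percentile estimator is Hyndman–Fan type 7 (linear interpolation of
order statistics at ``h = (n-1)p + 1``), matching the "R-7" definition
used for both the pathogenic 95th-percentile MAF threshold and the
sensitivity/specificity CADD thresholds.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["percentile_r7", "mann_whitney_u"]


def percentile_r7(values: Sequence[float], p: float) -> float:
    """Hyndman–Fan type-7 percentile of ``values`` at probability ``p``.

    Sort ascending as x[1..n]; h = (n-1)p + 1; return x[floor(h)]
    linearly interpolated toward x[floor(h)+1] by the fractional part
    of h.  p=0 gives the minimum, p=1 the maximum.

    Raises
    ------
    ValueError
        If ``values`` is empty, contains non-finite entries, or ``p``
        is outside [0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("percentile of an empty sequence is undefined")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    x = np.sort(x)
    n = x.size
    h = (n - 1) * p + 1.0
    if h <= 1.0:
        return float(x[0])
    if h >= n:
        return float(x[-1])
    lo = int(math.floor(h))  # 1-based index
    frac = h - lo
    return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test of ``a`` vs ``b``.

    Returns ``(U, p)`` where U is the statistic of ``a`` over ``b``
    (number of pairs (i, j) with a_i > b_j, ties counted 1/2).  Uses
    exact enumeration when both samples have n <= 8 and carry no ties,
    otherwise the tie-corrected normal approximation without continuity
    correction — so identical samples yield p = 1 exactly.  Degenerate
    inputs whose rank variance is zero (all values tied) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    # Tie-corrected normal approximation; guard the all-tied case where
    # the null variance of U collapses to zero.
    n1, n2 = a.size, b.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), 1.0
    res = _sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(min(1.0, res.pvalue))
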