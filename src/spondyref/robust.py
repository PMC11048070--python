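"""Robust location and scale: Hodges–Lehmann and the Rousseeuw–Croux Qn.

Both estimators are order statistics of O(n²) pairwise sets.  For small
samples they are computed by full enumeration; for large samples the k-th
pairwise value is found exactly by bisection on the value axis, using the
monotone pair-counting trick (count of pairs below a threshold costs
O(n log n) on sorted data), followed by an exact snap to the smallest
pairwise value above the bracket.  No subsampling is involved; results are
exact at every n.
"""
from __future__ import annotations

import numpy as np

#: Gaussian-consistency constant for Qn (Rousseeuw & Croux 1993)
QN_C = 2.2219

#: finite-sample correction factors d(n) for Qn (Croux & Rousseeuw 1992)
_QN_D_SMALL = {2: 0.399, 3: 0.994, 4: 0.512, 5: 0.844,
               6: 0.611, 7: 0.857, 8: 0.669, 9: 0.872}

_ENUM_MAX = 1024  # below this, enumerate all pairs outright


def qn_finite_sample_factor(n: int) -> float:
    """d(n) such that Qn is unbiased for sigma on Gaussian samples of size n."""
    if n in _QN_D_SMALL:
        return _QN_D_SMALL[n]
    if n % 2:
        return n / (n + 1.4)
    return n / (n + 3.8)


def _select_pairwise(x: np.ndarray, k: int, count, next_above, lo: float,
                     hi: float) -> float:
    """Exact k-th smallest (1-based) of an implicit pairwise multiset.

    `count(t)` returns how many pairwise values are <= t (monotone in t);
    `next_above(t)` returns the smallest pairwise value strictly above t
    (or +inf).  Invariant maintained: count(lo) < k <= count(hi).
    """
    if count(lo) >= k:
        return lo
    for _ in range(90):  # narrow to ~1e-14 relative; then snap exactly
        if hi <= np.nextafter(lo, hi):
            return hi
        mid = 0.5 * (lo + hi)
        if not (lo < mid < hi):
            return hi
        if count(mid) >= k:
            hi = mid
        else:
            lo = mid
    while True:
        v = next_above(lo)
        if v >= hi or count(v) >= k:
            return min(v, hi)
        lo = v


def hodges_lehmann(samples) -> float:
    """Median of all Walsh averages (x_i + x_j)/2, i <= j."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("hodges_lehmann needs at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("hodges_lehmann: non-finite values")
    total = n * (n + 1) // 2

    if n <= _ENUM_MAX:
        i, j = np.triu_indices(n)
        walsh = (x[i] + x[j]) / 2.0
        return float(np.median(walsh))

    def count(t):
        # pairs i <= j with x_i + x_j <= 2t
        idx = np.searchsorted(x, 2.0 * t - x, side="right")
        return int(np.sum(np.clip(idx - np.arange(n), 0, n - np.arange(n))))

    def next_above(t):
        # smallest Walsh average strictly greater than t
        j0 = np.searchsorted(x, 2.0 * t - x, side="right")
        j0 = np.maximum(j0, np.arange(n))
        ok = j0 < n
        if not np.any(ok):
            return np.inf
        return float(np.min((x[np.nonzero(ok)[0]] + x[j0[ok]]) / 2.0))

    lo, hi = x[0], x[-1]
    k_hi = total // 2 + 1
    v_hi = _select_pairwise(x, k_hi, count, next_above, lo, hi)
    if total % 2:
        return float(v_hi)
    v_lo = _select_pairwise(x, total // 2, count, next_above, lo, hi)
    return float(0.5 * (v_lo + v_hi))


def qn_scale(samples) -> float:
    """Qn = c * d(n) * {k-th smallest of |x_i - x_j|, i<j}, k = C(h,2),
    h = floor(n/2) + 1; consistent for the SD under normality."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("qn_scale needs at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("qn_scale: non-finite values")
    h = n // 2 + 1
    k = h * (h - 1) // 2
    scale = QN_C * qn_finite_sample_factor(n)

    if x[-1] == x[0]:
        return 0.0

    if n <= _ENUM_MAX:
        i, j = np.triu_indices(n, k=1)
        gaps = np.sort(x[j] - x[i])
        return float(scale * gaps[k - 1])

    def count(t):
        # pairs i < j with x_j - x_i <= t
        idx = np.searchsorted(x, x + t, side="right")
        return int(np.sum(idx - np.arange(n) - 1))

    def next_above(t):
        j0 = np.searchsorted(x, x + t, side="right")
        ok = j0 < n
        if not np.any(ok):
            return np.inf
        return float(np.min(x[j0[ok]] - x[np.nonzero(ok)[0]]))

    v = _select_pairwise(x, k, count, next_above, 0.0, float(x[-1] - x[0]))
    return float(scale * v)
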