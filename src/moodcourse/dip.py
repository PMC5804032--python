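"""Hartigan & Hartigan dip statistic for unimodality.

The dip of a distribution function ``F`` is the smallest sup-norm
distance from ``F`` to the class of unimodal CDFs (convex up to the
mode, concave after).  Large dips indicate multimodality; the empirical
dip of ``n`` distinct points is at least ``1/(2n)`` (attained by
perfectly uniform-spaced data).

Implementation notes
--------------------
For the empirical CDF of sorted distinct points ``x_1 < ... < x_n``, a
unimodal CDF within sup-distance ``d`` whose mode lies in the gap
``(x_j, x_(j+1))`` exists iff

* a convex function fits the bands ``[i/n - d, (i-1)/n + d]`` at
  ``x_1..x_j`` — in count units (delta = n d) the minimal ``2 n d``
  equals ``max(1, max_k (k + 1 - H_j(x_k)))`` with ``H_j`` the greatest
  convex minorant (lower hull) of the points ``(x_t, t)``, ``t <= j``;
* the mirror-image concave condition holds at ``x_(j+1)..x_n``;
* the two branches can be joined monotonically: the smallest reachable
  convex endpoint value ``E(d)`` at ``x_j`` must not exceed the largest
  reachable concave start value ``S(d)`` at ``x_(j+1)``.  ``E`` and
  ``S`` follow from chord extrapolations of the band bounds; the
  junction can only bind when ``d > 1/n`` and is resolved by bisection.

Side costs are monotone in the split index, so splits are screened by
their side-cost lower bound in ascending order with early stopping.
The mode-at-a-data-point (atom) case is never optimal for distinct
data; the test-suite cross-validates the whole function against a
linear-programming oracle built directly from the definition,
including atom splits.

The numeric core is compiled with numba when available (pure-Python
fallback otherwise); the Monte-Carlo null table makes thousands of
evaluations per series length.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError

__all__ = ["dip_statistic", "dip_monte_carlo_null"]

try:  # compiled kernels; falls back to pure python transparently
    from numba import njit
except ImportError:  # pragma: no cover - numba is normally installed
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _side_costs(x):
    """Convex-branch cost (in 2*n*d count units) for every prefix of x.

    F[j] is the minimal cost of fitting a convex CDF branch to the
    first j points.  The lower hull of the points (x_t, t) is grown
    incrementally; deviations of interior points above the hull only
    grow as the hull is cut lower, so the running maximum is updated on
    recomputed segments only.
    """
    n = len(x)
    F = np.zeros(n + 1)
    hull = np.empty(n, dtype=np.int64)
    nh = 0
    dev_max = 1.0
    for j in range(n):
        tj = j + 1.0
        while nh >= 2:
            a = hull[nh - 2]
            b = hull[nh - 1]
            if (x[b] - x[a]) * (tj - (b + 1.0)) - ((b + 1.0) - (a + 1.0)) * (x[j] - x[b]) > 0:
                break
            nh -= 1
        if nh >= 1:
            a = hull[nh - 1]
            if j - a > 1:
                ta = a + 1.0
                for k in range(a + 1, j):
                    h = ta + (tj - ta) * (x[k] - x[a]) / (x[j] - x[a])
                    d = (k + 1.0) + 1.0 - h
                    if d > dev_max:
                        dev_max = d
        hull[nh] = j
        nh += 1
        F[j + 1] = dev_max if dev_max > 1.0 else 1.0
    return F


@njit(cache=True)
def _convex_end_min(x, j, delta):
    """Smallest value at x[j-1] reachable by a delta-feasible convex branch.

    Count units: bands are [t - delta, t - 1 + delta] for t = 1..j.
    The binding bound is the steepest chord from an upper-band anchor
    (x_i, hi_i) through a lower-band point (x_k, lo_k), extrapolated to
    the endpoint, or the endpoint's own lower band.
    """
    e = j - delta
    xe = x[j - 1]
    for k in range(1, j - 1):          # 0-based; count = k + 1
        lo_k = (k + 1.0) - delta
        best_sl = -1e300
        for i in range(k):
            hi_i = i + delta           # count i+1 -> (i+1) - 1 + delta
            sl = (lo_k - hi_i) / (x[k] - x[i])
            if sl > best_sl:
                best_sl = sl
        v = lo_k + best_sl * (xe - x[k])
        if v > e:
            e = v
    return e


@njit(cache=True)
def _junction_ok(x, n, j, delta):
    """Can convex branch over x[:j] meet concave branch over x[j:]?"""
    if j == 0 or j == n:
        return True
    if delta <= 1.0:                   # canonical endpoints already ordered
        return True
    # E on the left side
    e = _convex_end_min(x[:j], j, delta)
    # S on the right side via the mirror image
    xm = -x[j:][::-1]
    s = n - _convex_end_min(xm, n - j, delta)
    return e <= s + 1e-12


@njit(cache=True)
def _split_cost(x, n, j, side_cost):
    """Exact cost (2*n*d units) of the split with mode in gap (x_j, x_j+1)."""
    delta0 = side_cost / 2.0
    if _junction_ok(x, n, j, delta0):
        return side_cost
    lo_d = delta0
    hi_d = 0.5 * n
    for _ in range(40):
        mid = 0.5 * (lo_d + hi_d)
        if _junction_ok(x, n, j, mid):
            hi_d = mid
        else:
            lo_d = mid
    return 2.0 * hi_d


@njit(cache=True)
def _dip_cost(x):
    """Dip times 2n for sorted distinct x (length >= 2)."""
    n = len(x)
    F = _side_costs(x)
    Gm = _side_costs(-x[::-1])
    L = np.empty(n + 1)
    for j in range(n + 1):
        g = Gm[n - j]
        L[j] = F[j] if F[j] > g else g
    order = np.argsort(L)
    best = 1e300
    for idx in range(n + 1):
        j = order[idx]
        if L[j] >= best:
            break
        c = _split_cost(x, n, j, L[j])
        if c < best:
            best = c
    return best


def dip_statistic(sample) -> float:
    """Dip statistic of a one-dimensional sample of distinct values.

    All-equal input returns 0 (a point mass is unimodal).  Partially
    tied input is rejected: an atom at the mode makes the tied case
    structurally different, and all callers in this package jitter
    integer scores before testing, which makes ties a.s. impossible.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    if np.any(np.diff(x) == 0):
        raise ValueError(
            "dip_statistic requires distinct values; jitter discrete scores "
            "first, as dip_test does"
        )
    return float(_dip_cost(x)) / (2.0 * n)


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def dip_monte_carlo_null(n: int, n_reps: int = 2000, seed: int = 12345) -> np.ndarray:
    """Seeded Monte-Carlo null distribution of the dip for uniform samples.

    The dip is location/scale invariant, so uniform(0, 1) samples give
    the null for any continuous sample of the same size ``n``.  Results
    are cached per (n, n_reps, seed) because the null is shared by every
    patient with the same series length.
    """
    if n < 2:
        raise InsufficientDataError("dip null needs n >= 2")
    key = (n, n_reps, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        vals = np.empty(n_reps)
        for i in range(n_reps):
            vals[i] = dip_statistic(rng.random(n))
        _NULL_CACHE[key] = vals
    return _NULL_CACHE[key]
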