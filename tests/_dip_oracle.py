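"""Independent LP oracle for the dip statistic.

Minimises the sup-distance d subject to existence of a unimodal CDF
(convex to the mode, concave after, an atom allowed only at the mode)
within d of the empirical CDF.  The mode position is enumerated over
every gap between order statistics and every data point (atom case);
constraints are written directly from the definition: band constraints
from the step-function sup-norm, second-difference convexity /
concavity, monotonicity, and values in [0, 1].
"""

import numpy as np
from scipy.optimize import linprog


def _lp_gap(x, j):
    """Min d with the mode in the gap (x_j, x_{j+1}); j in 0..n."""
    n = len(x)
    A, b = [], []

    def row(coeffs, rhs):
        r = np.zeros(n + 1)
        for k, v in coeffs:
            r[k] += v
        A.append(r)
        b.append(rhs)

    for i in range(n):
        row([(i, 1.0), (n, -1.0)], i / n)            # g_i <= (i)/n + d
        row([(i, -1.0), (n, -1.0)], -(i + 1) / n)    # g_i >= (i+1)/n - d
    for i in range(n - 1):
        row([(i, 1.0), (i + 1, -1.0)], 0.0)          # monotone
    for i in range(1, n - 1):
        dx1, dx2 = x[i] - x[i - 1], x[i + 1] - x[i]
        coeffs = [(i - 1, -1.0 / dx1), (i, 1.0 / dx1 + 1.0 / dx2),
                  (i + 1, -1.0 / dx2)]
        if i + 1 <= j - 1:                           # convex region
            row(coeffs, 0.0)
        if i - 1 >= j:                               # concave region
            row([(k, -v) for k, v in coeffs], 0.0)
    bounds = [(0.0, 1.0)] * n + [(0.0, None)]
    c = np.zeros(n + 1)
    c[n] = 1.0
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    return res.fun if res.success else np.inf


def _lp_atom(x, p):
    """Min d with an atom at x_p; the CDF may jump there."""
    n = len(x)
    GL, D = n, n + 1
    A, b = [], []

    def row(coeffs, rhs):
        r = np.zeros(n + 2)
        for k, v in coeffs:
            r[k] += v
        A.append(r)
        b.append(rhs)

    for i in range(n):
        if i == p:
            row([(GL, 1.0), (D, -1.0)], i / n)       # left limit upper band
            row([(i, -1.0), (D, -1.0)], -(i + 1) / n)
        else:
            row([(i, 1.0), (D, -1.0)], i / n)
            row([(i, -1.0), (D, -1.0)], -(i + 1) / n)
    for i in range(n - 1):
        upper = GL if i + 1 == p else i + 1
        row([(i, 1.0), (upper, -1.0)], 0.0)
    row([(GL, 1.0), (p, -1.0)], 0.0)                 # jump goes upward

    def val(i):
        return GL if i == p else i

    for i in range(1, n - 1):
        dx1, dx2 = x[i] - x[i - 1], x[i + 1] - x[i]
        if i + 1 <= p:                               # convex incl. left limit
            row([(val(i - 1), -1.0 / dx1), (val(i), 1.0 / dx1 + 1.0 / dx2),
                 (val(i + 1), -1.0 / dx2)], 0.0)
        if i - 1 >= p:                               # concave from the atom
            row([(i - 1, 1.0 / dx1), (i, -1.0 / dx1 - 1.0 / dx2),
                 (i + 1, 1.0 / dx2)], 0.0)
    bounds = [(0.0, 1.0)] * (n + 1) + [(0.0, None)]
    c = np.zeros(n + 2)
    c[D] = 1.0
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    return res.fun if res.success else np.inf


def lp_dip(x):
    """Exact dip of a sorted distinct sample by LP over all mode positions."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    best = min(_lp_gap(x, j) for j in range(n + 1))
    best_atom = min(_lp_atom(x, p) for p in range(n))
    return min(best, best_atom)
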