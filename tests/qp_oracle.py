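"""Exact brute-force oracle for small box-constrained QPs.

Enumerates every active-set configuration (each variable at its lower
bound, upper bound, or free), solves the free subsystem, and keeps the
best feasible stationary point.  Exponential in n, exact to machine
precision — usable up to n ~ 10.
"""

import itertools

import numpy as np


def oracle_box_qp(M: np.ndarray, q: np.ndarray, ub: float) -> tuple[np.ndarray, float]:
    """Global minimizer of 0.5 x'Mx + q'x over [0, ub]^n by enumeration."""
    n = len(q)
    best_x, best_f = None, np.inf
    for assignment in itertools.product((0, 1, 2), repeat=n):
        x = np.empty(n)
        free = [i for i, a in enumerate(assignment) if a == 2]
        for i, a in enumerate(assignment):
            if a == 0:
                x[i] = 0.0
            elif a == 1:
                x[i] = ub
        if free:
            fixed = [i for i in range(n) if i not in free]
            rhs = -(q[free] + (M[np.ix_(free, fixed)] @ x[fixed] if fixed else 0.0))
            try:
                x[free] = np.linalg.solve(M[np.ix_(free, free)], rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(x[free] < -1e-10) or np.any(x[free] > ub + 1e-10):
                continue
        f = 0.5 * x @ M @ x + q @ x
        if f < best_f - 1e-15:
            best_f, best_x = f, np.clip(x, 0.0, ub)
    return best_x, float(best_f)
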