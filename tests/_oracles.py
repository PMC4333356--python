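"""Independent oracles used by the tests.

These deliberately avoid the package's own evaluation paths: the heat
solution with Neumann ends is represented by the method of images (erfc
form, numerically exact even deep in the front tail where the cosine
series cancels catastrophically), and tridiagonal systems are solved
densely with LAPACK.
"""

import math

import numpy as np
from scipy.special import erfc


def heat_neumann_step(xi: float, T: float, beta: float, C0: float = 1.0,
                      L0: float = 1.0, images: int = 8) -> float:
    """u(xi, T) for du/dT = d2u/dxi2 on [0, 1], zero-flux ends,
    u(xi, 0) = C0 on [0, beta/L0).

    Method of images: the even, 2-periodic extension of the step is a union
    of intervals (2m - b, 2m + b) with b = beta/L0; convolving with the
    free-space heat kernel gives a sum of erf differences, evaluated here
    via erfc so that near-1 cancellation never occurs.
    """
    if T == 0.0:
        return C0 if xi < beta / L0 else 0.0
    b = beta / L0
    s = 2.0 * math.sqrt(T)
    tot = 0.0
    for m in range(-images, images + 1):
        lo = (xi - 2.0 * m - b) / s
        hi = (xi - 2.0 * m + b) / s
        if lo >= 0.0:
            tot += 0.5 * (erfc(lo) - erfc(hi))
        elif hi <= 0.0:
            tot += 0.5 * (erfc(-hi) - erfc(-lo))
        else:
            tot += 0.5 * (2.0 - erfc(-lo) - erfc(hi))
    return C0 * tot


def exact_solution_images(problem, xi: float, t: float) -> float:
    """Full growing-domain solution via the image oracle (step IC only)."""
    gm = problem.growth
    T = gm.rescaled_time(problem.D, t)
    g = math.exp(problem.k * t) * gm.L0 / gm.length(t)
    return g * heat_neumann_step(xi, T, problem.ic.beta, problem.ic.C0, gm.L0)


def dense_tridiagonal_solve(lower, diag, upper, rhs) -> np.ndarray:
    """Dense LAPACK solve of a tridiagonal system."""
    n = len(diag)
    A = np.diag(np.asarray(diag, dtype=float))
    A += np.diag(np.asarray(lower, dtype=float), -1)
    A += np.diag(np.asarray(upper, dtype=float), 1)
    return np.linalg.solve(A, np.asarray(rhs, dtype=float))
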