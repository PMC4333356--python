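"""Exact Fourier-series solution on a uniformly growing domain.

Separation of variables in the fixed coordinate xi = x / L(t) and the
rescaled time T(t) = int_0^t D / L^2 ds gives the exact solution

    C(x, t) = (L(0) / L(t)) exp(k t)
              * sum_n a_n cos(n pi x / L(t)) exp(-(n pi)^2 T(t)),

where the a_n are the cosine coefficients of the initial profile on
[0, L(0)].  The prefactor uses the identity

    exp( int_0^t (k - sigma(s)) ds ) = exp(k t) L(0) / L(t),

valid for any growth law, so a single evaluator (:func:`evaluate_exact`)
covers static, exponential, linear and custom growth.  The literal per-case
closed forms (:func:`evaluate_case_formula`) are retained as an independent
cross-check, together with the classical two-term long-time truncation on a
static domain (:func:`two_term_longtime_approx`) -- a truncation that is
deliberately *refused* on growing domains, where T(t) saturates at a finite
value and higher modes never die out relative to the leading ones.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

from .exceptions import (
    InputError,
    OverflowGuardError,
    ParameterError,
    UnsupportedCaseError,
)
from .problem import FourierCoefficients, InitialCondition, Problem, Profile

__all__ = [
    "step_fourier_coefficients",
    "general_fourier_coefficients",
    "fourier_coefficients",
    "evaluate_exact",
    "evaluate_case_formula",
    "two_term_longtime_approx",
]

#: default series truncation order
DEFAULT_N_MAX = 1000

#: largest exponent passed to exp() before raising OverflowGuardError
_EXP_GUARD = 700.0


def step_fourier_coefficients(ic: InitialCondition, L0: float, n_max: int = DEFAULT_N_MAX,
                              ) -> FourierCoefficients:
    """Closed-form cosine coefficients of the step initial condition.

    a_0 = beta C0 / L0 and a_n = (2 C0 / (n pi)) sin(n pi beta / L0).
    These are the growth-free coefficients; any growth- or reaction-dependent
    factor belongs to the series prefactor, not to the coefficients.
    """
    if ic.kind != "step":
        raise ParameterError("step_fourier_coefficients requires a step initial condition")
    if n_max < 1:
        raise ParameterError(f"n_max must be >= 1, got {n_max}")
    if ic.beta > L0 * (1 + 1e-12):
        raise ParameterError(f"beta = {ic.beta} exceeds L0 = {L0}")
    n = np.arange(1, n_max + 1)
    values = np.empty(n_max + 1)
    values[0] = ic.beta * ic.C0 / L0
    values[1:] = (2.0 * ic.C0 / (n * np.pi)) * np.sin(n * np.pi * ic.beta / L0)
    return FourierCoefficients(values)


def general_fourier_coefficients(ic: InitialCondition, L0: float, n_max: int = 50,
                                 ) -> FourierCoefficients:
    """Cosine coefficients of an arbitrary initial profile by quadrature.

    a_0 = (1/L0) int_0^L0 C(x,0) dx and
    a_n = (2/L0) int_0^L0 C(x,0) cos(n pi x / L0) dx.
    """
    if ic.kind != "general":
        raise ParameterError("general_fourier_coefficients requires a general initial condition")
    if n_max < 1:
        raise ParameterError(f"n_max must be >= 1, got {n_max}")

    def f(x: float) -> float:
        v = float(ic.profile(x))
        if not math.isfinite(v):
            raise InputError(f"initial profile returned non-finite value at x = {x}")
        return v

    values = np.empty(n_max + 1)
    values[0] = quad(f, 0.0, L0, limit=200)[0] / L0
    for n in range(1, n_max + 1):
        w = n * np.pi / L0
        # weight='cos' integrates f(x) cos(w x) accurately for oscillatory modes
        values[n] = 2.0 / L0 * quad(f, 0.0, L0, weight="cos", wvar=w, limit=200)[0]
    return FourierCoefficients(values)


def fourier_coefficients(ic: InitialCondition, L0: float, n_max: int = DEFAULT_N_MAX,
                         ) -> FourierCoefficients:
    """Dispatch to the closed-form (step) or quadrature (general) coefficients."""
    if ic.kind == "step":
        return step_fourier_coefficients(ic, L0, n_max)
    return general_fourier_coefficients(ic, L0, min(n_max, 200))


def _log_growth_factor(problem: Problem, t: float, L: float) -> float:
    """log of exp(kt) L(0) / L(t), with an overflow guard."""
    logg = problem.k * t + math.log(problem.growth.L0) - math.log(L)
    if logg > _EXP_GUARD:
        raise OverflowGuardError(
            f"growth factor exp({logg:.1f}) overflows double precision at t = {t}; "
            "the reaction term k t is too large for a direct evaluation"
        )
    return logg


def _as_xi(grid, coordinate: str, L: float) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise InputError("grid must be a non-empty 1-D array")
    if coordinate == "x":
        if grid[0] < -1e-12 or grid[-1] > L * (1 + 1e-12):
            raise InputError(f"physical grid must lie within [0, {L}]")
        return grid / L
    if coordinate == "xi":
        if grid[0] < -1e-12 or grid[-1] > 1 + 1e-12:
            raise InputError("fixed-domain grid must lie within [0, 1]")
        return grid
    raise InputError(f"coordinate must be 'x' or 'xi', got {coordinate!r}")


def evaluate_exact(problem: Problem, grid, t: float, n_max: int = DEFAULT_N_MAX,
                   coordinate: str = "x") -> Profile:
    """Evaluate the exact series solution at time ``t`` on ``grid``.

    Parameters
    ----------
    problem
        Growth law, D, k and initial condition.
    grid
        Strictly increasing positions: physical x in [0, L(t)] when
        ``coordinate="x"``, or fixed xi in [0, 1] when ``coordinate="xi"``.
    t
        Evaluation time (>= 0).
    n_max
        Series truncation order; the default keeps 1001 cosine modes.

    Returns
    -------
    Profile
        Snapshot in the requested coordinate.  At t = 0 a step initial
        condition exhibits the usual Gibbs oscillation near the jump; no
        smoothing is applied.
    """
    t = float(t)
    if t < 0:
        raise InputError(f"time must be >= 0, got {t}")
    L = problem.growth.length(t)
    xi = _as_xi(grid, coordinate, L)
    coeffs = fourier_coefficients(problem.ic, problem.growth.L0, n_max)
    T = problem.growth.rescaled_time(problem.D, t)
    g = math.exp(_log_growth_factor(problem, t, L))
    n = np.arange(coeffs.values.size)
    mode_amp = coeffs.values * np.exp(-((n * np.pi) ** 2) * T)
    values = g * (np.cos(np.outer(xi, n * np.pi)) @ mode_amp)
    return Profile(t=t, coordinate=coordinate, grid=np.asarray(grid, dtype=float),
                   values=values)


def evaluate_case_formula(problem: Problem, grid, t: float, n_max: int = DEFAULT_N_MAX,
                          coordinate: str = "x") -> Profile:
    """Evaluate the literal per-case closed form (step IC only).

    Static:       C = sum a_n cos(n pi x / L) exp(-D (n pi)^2 t / L^2 + k t)
    Exponential:  C = sum a_n cos(n pi x / L(t))
                        * exp(-D (n pi)^2 (1 - e^{-2 alpha t}) / (2 alpha L0^2)
                              + t (k - alpha))
    Linear:       C = sum a_n' (L0 / L(t)) cos(n pi x / L(t))
                        * exp(-(n pi)^2 D t / (L0 L(t)) + k L(t) / b),
                  with a_n' carrying the extra factor exp(-k L0 / b).

    Kept deliberately separate from :func:`evaluate_exact` as an independent
    cross-check of the unified growth-factor identity.
    """
    if problem.ic.kind != "step":
        raise UnsupportedCaseError("case formulas are defined for the step initial condition")
    case = problem.growth.case
    if case not in ("static", "exponential", "linear"):
        raise UnsupportedCaseError(f"no printed closed form for growth case {case!r}")
    t = float(t)
    if t < 0:
        raise InputError(f"time must be >= 0, got {t}")
    gm, D, k = problem.growth, problem.D, problem.k
    L0, L = gm.L0, gm.length(t)
    xi = _as_xi(grid, coordinate, L)
    coeffs = step_fourier_coefficients(problem.ic, L0, n_max)
    n = np.arange(coeffs.values.size)
    npi = n * np.pi

    if case == "static":
        expo = -D * npi**2 * t / L0**2 + k * t
        amp = coeffs.values
    elif case == "exponential":
        expo = -D * npi**2 * -math.expm1(-2.0 * gm.alpha * t) / (2.0 * gm.alpha * L0**2) \
            + t * (k - gm.alpha)
        amp = coeffs.values
    else:  # linear
        expo = -npi**2 * D * t / (L0 * L) + k * L / gm.b
        amp = coeffs.values * math.exp(-k * L0 / gm.b) * (L0 / L)
    if np.max(expo) > _EXP_GUARD:
        raise OverflowGuardError(
            f"case-formula exponent {np.max(expo):.1f} overflows double precision at t = {t}"
        )
    values = np.cos(np.outer(xi, npi)) @ (amp * np.exp(expo))
    return Profile(t=t, coordinate=coordinate, grid=np.asarray(grid, dtype=float),
                   values=values)


def two_term_longtime_approx(problem: Problem, grid, t: float,
                             coordinate: str = "x") -> Profile:
    """Two-term long-time truncation, static domains only.

    C(x, t) ~ (beta C0 / L0) e^{k t}
              + (2 C0 / pi) sin(pi beta / L0) cos(pi x / L0) e^{-D pi^2 t / L0^2 + k t}.

    On a growing domain the rescaled time saturates, the higher modes never
    become negligible, and a two-term truncation is badly wrong at every
    time; the function refuses with :class:`UnsupportedCaseError` instead of
    silently approximating.
    """
    if problem.growth.case != "static":
        raise UnsupportedCaseError(
            "the two-term long-time truncation is valid only on a static domain; "
            "on growing domains the rescaled time saturates and truncation is unreliable"
        )
    if problem.ic.kind != "step":
        raise UnsupportedCaseError("two-term approximation is defined for the step initial condition")
    t = float(t)
    if t < 0:
        raise InputError(f"time must be >= 0, got {t}")
    gm, D, k, ic = problem.growth, problem.D, problem.k, problem.ic
    L0 = gm.L0
    xi = _as_xi(grid, coordinate, L0)
    if k * t > _EXP_GUARD:
        raise OverflowGuardError(f"exp(k t) overflows double precision at t = {t}")
    values = (ic.beta * ic.C0 / L0) * math.exp(k * t) \
        + (2.0 * ic.C0 / math.pi) * math.sin(math.pi * ic.beta / L0) \
        * np.cos(math.pi * xi) * math.exp(-D * math.pi**2 * t / L0**2 + k * t)
    return Profile(t=t, coordinate=coordinate, grid=np.asarray(grid, dtype=float),
                   values=values)
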