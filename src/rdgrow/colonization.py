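"""Front tracking and the colonization criterion.

The front f(t) of a spreading density profile is the rightmost position
where C(x, t) crosses a small threshold density epsilon (0.01 in the worked
examples, with C0 = 1).  The domain is *colonized* at time t when the
density at the moving far boundary exceeds the threshold,
C(L(t), t) > epsilon -- equivalently, when the front has reached the
boundary.  These definitions, together with a first-colonization-time
search, summarize whether a profile initially confined near the fixed end
overcomes domain growth: the biological question of whether neural-crest
precursor cells fully occupy an elongating gut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import InputError, ParameterError
from .fd import FDGrid, solve_fd
from .growth import GrowthModel
from .problem import Problem, Profile
from .series import DEFAULT_N_MAX, evaluate_exact, fourier_coefficients

__all__ = [
    "FRONT", "COLONIZED", "EXTINCT",
    "front_position", "front_trace", "FrontTrace",
    "colonization_test", "colonization_time", "ColonizationResult",
    "total_mass",
]

#: status labels for a front determination
FRONT = "front"          # a threshold crossing strictly inside the domain
COLONIZED = "colonized"  # density above threshold at the far boundary
EXTINCT = "extinct"      # density below threshold everywhere

#: default number of fixed-xi nodes used to locate fronts
DEFAULT_RESOLUTION = 2001


def front_position(profile: Profile, epsilon: float) -> Tuple[str, Optional[float]]:
    """Locate the front of a density snapshot.

    Returns ``(status, position)``:

    * ``("colonized", grid[-1])`` if the density at the right end exceeds
      ``epsilon``;
    * ``("front", x*)`` with x* the *rightmost* downward crossing of the
      level ``epsilon``, linearly interpolated between the bracketing
      nodes -- the rightmost-crossing rule makes the front insensitive to
      Gibbs oscillations of the truncated series near a step discontinuity;
    * ``("extinct", None)`` if the density is below ``epsilon`` everywhere.

    Positions are in the profile's own coordinate (physical x or fixed xi).
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be > 0, got {epsilon}")
    v = profile.values
    x = profile.grid
    if v[-1] > epsilon:
        return COLONIZED, float(x[-1])
    above = v > epsilon
    if not above.any():
        return EXTINCT, None
    # rightmost i with v[i] > eps and v[i+1] <= eps
    i = int(np.nonzero(above[:-1] & ~above[1:])[0][-1])
    frac = (v[i] - epsilon) / (v[i] - v[i + 1])
    return FRONT, float(x[i] + frac * (x[i + 1] - x[i]))


@dataclass(frozen=True)
class FrontTrace:
    """Space-time summary: domain length L(t) and front position f(t).

    ``fronts[i]`` equals L(t) where the status is ``colonized`` and NaN
    where ``extinct``; ``gap()`` returns L(t) - f(t).
    """

    times: np.ndarray
    lengths: np.ndarray
    fronts: np.ndarray
    statuses: List[str]
    epsilon: float

    def gap(self) -> np.ndarray:
        return self.lengths - self.fronts


def _profiles_at(problem: Problem, times: Sequence[float], method: str,
                 resolution: int, n_max: int,
                 fd_grid: Optional[FDGrid]) -> List[Profile]:
    """Fixed-xi profiles at the requested times from the chosen solver."""
    if method == "exact":
        xi = np.linspace(0.0, 1.0, resolution)
        return [evaluate_exact(problem, xi, t, n_max=n_max, coordinate="xi")
                for t in times]
    if method == "fd":
        grid = fd_grid if fd_grid is not None else FDGrid()
        return solve_fd(problem, grid, times)
    raise ParameterError(f"method must be 'exact' or 'fd', got {method!r}")


def front_trace(problem: Problem, epsilon: float, times: Sequence[float],
                method: str = "exact", resolution: int = DEFAULT_RESOLUTION,
                n_max: int = DEFAULT_N_MAX,
                fd_grid: Optional[FDGrid] = None) -> FrontTrace:
    """Track L(t) and f(t) over a list of increasing times.

    At t = 0 with a step initial condition the front is placed exactly at
    the jump, f(0) = beta (every level between 0 and C0 is crossed at the
    discontinuity itself), rather than read off a truncated series whose
    Gibbs oscillation would blur the jump.
    """
    times = [float(t) for t in times]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise InputError("times must be strictly increasing")
    profiles = _profiles_at(problem, times, method, resolution, n_max, fd_grid)
    lengths = np.array([problem.growth.length(t) for t in times])
    fronts = np.empty(len(times))
    statuses: List[str] = []
    for j, (t, prof, L) in enumerate(zip(times, profiles, lengths)):
        if t == 0.0 and problem.ic.kind == "step":
            ic = problem.ic
            if ic.C0 <= epsilon:
                status, pos = EXTINCT, None
            elif ic.beta >= problem.growth.L0:
                status, pos = COLONIZED, problem.growth.L0
            else:
                status, pos = FRONT, ic.beta
        else:
            status, pos = front_position(prof, epsilon)
            if pos is not None:
                pos *= L  # fixed-xi profile -> physical position
        statuses.append(status)
        fronts[j] = math.nan if pos is None else pos
    return FrontTrace(times=np.asarray(times), lengths=lengths, fronts=fronts,
                      statuses=statuses, epsilon=float(epsilon))


def _boundary_density(problem: Problem, t: float, method: str,
                      n_max: int, fd_grid: Optional[FDGrid]) -> float:
    """Density at the moving boundary, C(L(t), t).

    For the exact method the series is evaluated at xi = 1, where
    cos(n pi) = (-1)^n.  Deep in the front tail the alternating sum cancels
    down to ~1e-16 of its term magnitudes while a strong reaction term
    amplifies it by exp(k t), so the sum is accumulated in extended
    precision (long double) to keep the boundary value's *relative* error
    small; the growth/reaction factor is applied in the log domain so that
    very late times (where the boundary density is astronomically large)
    report ``inf`` rather than overflowing.
    """
    if method == "exact":
        t = float(t)
        L = problem.growth.length(t)
        T = problem.growth.rescaled_time(problem.D, t)
        if problem.ic.kind == "step":
            # closed-form coefficients, recomputed in long double: their
            # last-bit rounding alone can dominate the cancelled sum
            ld = np.longdouble
            n = np.arange(1, n_max + 1, dtype=ld)
            pi = ld(np.pi)
            a = (2 * ld(problem.ic.C0) / (n * pi)) \
                * np.sin(n * pi * ld(problem.ic.beta) / ld(problem.growth.L0))
            sign = np.where(np.arange(1, n_max + 1) % 2 == 0, 1.0, -1.0).astype(ld)
            terms = a * sign * np.exp(-(pi * n) ** 2 * ld(T))
            s = ld(problem.ic.beta * problem.ic.C0 / problem.growth.L0) \
                + np.sum(terms[::-1])  # small terms first
        else:
            coeffs = fourier_coefficients(problem.ic, problem.growth.L0, n_max)
            n = np.arange(coeffs.values.size)
            sign = np.where(n % 2 == 0, 1.0, -1.0).astype(np.longdouble)
            terms = coeffs.values.astype(np.longdouble) * sign \
                * np.exp(-np.longdouble(np.pi) ** 2 * n.astype(np.longdouble) ** 2
                         * np.longdouble(T))
            s = np.sum(terms[::-1])
        logg = problem.k * t + math.log(problem.growth.L0) - math.log(L)
        if s <= 0.0:
            # truncated-series zero crossing of the far tail (or t = 0)
            return float(math.exp(min(logg, 700.0)) * float(s))
        log_c = logg + math.log(float(s))
        if log_c > 700.0:
            return math.inf
        return math.exp(log_c)
    grid = fd_grid if fd_grid is not None else FDGrid()
    return float(solve_fd(problem, grid, [t])[0].values[-1])


def colonization_test(problem: Problem, epsilon: float, t_star: float,
                      method: str = "exact", n_max: int = DEFAULT_N_MAX,
                      fd_grid: Optional[FDGrid] = None) -> bool:
    """Is the domain colonized at ``t_star``, i.e. C(L(t*), t*) > epsilon?

    The inequality is strict, so the measure-zero boundary case
    C(L(t*), t*) == epsilon reports not colonized.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be > 0, got {epsilon}")
    if t_star < 0:
        raise InputError(f"t_star must be >= 0, got {t_star}")
    if method not in ("exact", "fd"):
        raise ParameterError(f"method must be 'exact' or 'fd', got {method!r}")
    return _boundary_density(problem, t_star, method, n_max, fd_grid) > epsilon


@dataclass(frozen=True)
class ColonizationResult:
    """Outcome of a first-colonization-time search up to ``horizon``.

    ``transitions`` lists every change of colonization status detected on
    the coarse scan, as ``(time, colonized_after)`` pairs; normally there is
    a single False -> True transition, but none is assumed.
    """

    colonized: bool
    time: Optional[float]
    horizon: float
    epsilon: float
    transitions: Tuple[Tuple[float, bool], ...] = field(default_factory=tuple)


def colonization_time(problem: Problem, epsilon: float, t_max: float,
                      method: str = "exact", n_max: int = DEFAULT_N_MAX,
                      fd_grid: Optional[FDGrid] = None,
                      n_scan: int = 200, time_tol: float = 0.01) -> ColonizationResult:
    """First time at which the colonization test succeeds, within [0, t_max].

    A coarse forward scan over ``n_scan`` equal steps locates the first
    bracket where the status flips to colonized; bisection then refines the
    earliest flip to ``time_tol``.  If no scan point succeeds the result
    reports not colonized (the scan can in principle step over an interval
    of colonization narrower than t_max / n_scan).
    """
    if t_max <= 0:
        raise InputError(f"t_max must be > 0, got {t_max}")
    ts = np.linspace(0.0, t_max, n_scan + 1)
    flags = [colonization_test(problem, epsilon, t, method=method, n_max=n_max,
                               fd_grid=fd_grid) for t in ts]
    transitions = tuple((float(ts[i]), flags[i])
                        for i in range(1, len(ts)) if flags[i] != flags[i - 1])
    if flags[0]:
        return ColonizationResult(True, 0.0, float(t_max), float(epsilon), transitions)
    first = next((i for i, f in enumerate(flags) if f), None)
    if first is None:
        return ColonizationResult(False, None, float(t_max), float(epsilon), transitions)
    lo, hi = float(ts[first - 1]), float(ts[first])
    while hi - lo > time_tol:
        mid = 0.5 * (lo + hi)
        if colonization_test(problem, epsilon, mid, method=method, n_max=n_max,
                             fd_grid=fd_grid):
            hi = mid
        else:
            lo = mid
    return ColonizationResult(True, 0.5 * (lo + hi), float(t_max), float(epsilon),
                              transitions)


def total_mass(profile: Profile, growth: GrowthModel) -> float:
    """Trapezoid integral of the profile over physical x.

    With zero-flux boundaries the exact solution satisfies the mass law
    M(t) = M(0) exp(k t); this diagnostic lets callers check it.
    """
    x = profile.physical_grid(growth)
    return float(np.trapezoid(profile.values, x))
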