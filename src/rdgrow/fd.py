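"""Finite-difference reference solver on the fixed domain.

Discretizes the transformed equation

    dC/dt = (D / L^2(t)) d2C/dxi2 + (k - sigma(t)) C,   0 < xi < 1,

with central second differences on a uniform xi-mesh, backward Euler in
time (coefficients evaluated at the new time level, so each step is fully
implicit and unconditionally stable), zero-flux ends closed by ghost-node
mirroring (C_{-1} = C_1, C_{N+1} = C_{N-1}), and a Thomas (tridiagonal
forward-elimination / back-substitution) solve per step.  The scheme is the
numerical cross-check for the exact series solution, not a production PDE
solver: no adaptive stepping, no higher-order time integrator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

try:  # Thomas kernel is JIT-compiled when numba is available
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]

from .exceptions import InputError, ParameterError, SolverError
from .problem import Problem, Profile

__all__ = [
    "FDGrid",
    "TridiagonalSystem",
    "thomas_solve",
    "assemble_step",
    "solve_fd",
    "grid_independence_check",
    "GridIndependenceReport",
]


@dataclass(frozen=True)
class FDGrid:
    """Uniform space-time mesh: node j at xi = j * delta_xi, steps of delta_t."""

    delta_xi: float = 0.001
    delta_t: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.delta_xi <= 0.5):
            raise ParameterError(f"delta_xi must be in (0, 0.5], got {self.delta_xi}")
        if self.delta_t <= 0:
            raise ParameterError(f"delta_t must be > 0, got {self.delta_t}")
        n = 1.0 / self.delta_xi
        if abs(n - round(n)) > 1e-9 * n:
            raise ParameterError(f"1/delta_xi must be an integer, got {n}")

    @property
    def n_cells(self) -> int:
        return round(1.0 / self.delta_xi)

    @property
    def nodes(self) -> int:
        return self.n_cells + 1

    @property
    def xi(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.nodes)

    def halved(self) -> "FDGrid":
        """The refined mesh with both steps halved."""
        return FDGrid(delta_xi=self.delta_xi / 2.0, delta_t=self.delta_t / 2.0)


@dataclass
class TridiagonalSystem:
    """Tridiagonal linear system: ``lower``/``upper`` hold the off-diagonals
    (length n-1), ``diagonal`` and ``rhs`` length n."""

    lower: np.ndarray
    diagonal: np.ndarray
    upper: np.ndarray
    rhs: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.diagonal = np.asarray(self.diagonal, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.rhs = np.asarray(self.rhs, dtype=float)
        n = self.diagonal.size
        if self.rhs.size != n or self.lower.size != n - 1 or self.upper.size != n - 1:
            raise InputError("inconsistent tridiagonal system dimensions")


@_njit(cache=True)
def _thomas_kernel(lower, diag, upper, rhs):  # pragma: no cover - exercised via wrapper
    n = diag.size
    cp = np.empty(n)
    dp = np.empty(n)
    if diag[0] == 0.0:
        return np.empty(0), 0
    cp[0] = upper[0] / diag[0] if n > 1 else 0.0
    dp[0] = rhs[0] / diag[0]
    for i in range(1, n):
        denom = diag[i] - lower[i - 1] * cp[i - 1]
        if denom == 0.0:
            return np.empty(0), i
        cp[i] = upper[i] / denom if i < n - 1 else 0.0
        dp[i] = (rhs[i] - lower[i - 1] * dp[i - 1]) / denom
    x = np.empty(n)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x, -1


def thomas_solve(system: TridiagonalSystem) -> np.ndarray:
    """Solve a tridiagonal system by the Thomas algorithm (O(n), no pivoting).

    Raises :class:`SolverError` on a zero pivot.  Backward-Euler diffusion
    systems are strictly diagonally dominant, so no pivoting is needed there.
    """
    x, bad = _thomas_kernel(system.lower, system.diagonal, system.upper, system.rhs)
    if bad >= 0:
        raise SolverError(f"singular tridiagonal system: zero pivot at row {bad}")
    return x


def assemble_step(problem: Problem, grid: FDGrid, t_new: float,
                  state: np.ndarray) -> TridiagonalSystem:
    """Assemble the backward-Euler system (I - dt A(t_new)) C_new = C_old.

    A is the central-difference Laplacian scaled by D / L^2(t_new) plus
    (k - sigma(t_new)) I; the boundary rows double the single off-diagonal
    (ghost-node mirror closure of the zero-flux condition).
    """
    state = np.asarray(state, dtype=float)
    if state.size != grid.nodes:
        raise InputError(f"state has {state.size} entries, expected {grid.nodes}")
    L = problem.growth.length(t_new)
    sig = problem.growth.sigma(t_new)
    r = grid.delta_t * problem.D / (L * L * grid.delta_xi**2)
    react = grid.delta_t * (problem.k - sig)
    n = grid.nodes
    diag = np.full(n, 1.0 + 2.0 * r - react)
    lower = np.full(n - 1, -r)
    upper = np.full(n - 1, -r)
    upper[0] = -2.0 * r
    lower[-1] = -2.0 * r
    return TridiagonalSystem(lower=lower, diagonal=diag, upper=upper, rhs=state.copy())


def initial_state(problem: Problem, grid: FDGrid) -> np.ndarray:
    """Initial nodal values on the xi-mesh.

    For the step condition, nodes with x strictly below beta get C0 and the
    node at (or beyond) beta gets 0, matching the half-open interval of the
    step definition.
    """
    x = grid.xi * problem.growth.L0
    if problem.ic.kind == "step":
        tol = 1e-12 * max(problem.growth.L0, 1.0)
        return np.where(x < problem.ic.beta - tol, problem.ic.C0, 0.0)
    return np.asarray(problem.ic(x, problem.growth.L0), dtype=float)


def solve_fd(problem: Problem, grid: FDGrid,
             output_times: Sequence[float]) -> List[Profile]:
    """March the backward-Euler scheme and return fixed-xi profiles.

    ``output_times`` must be sorted and non-negative; each is snapped to the
    nearest multiple of ``delta_t`` and the snapped time is recorded in the
    returned :class:`~rdgrow.problem.Profile`.
    """
    times = [float(t) for t in output_times]
    if any(t < 0 for t in times) or any(b < a for a, b in zip(times, times[1:])):
        raise InputError("output_times must be sorted and >= 0")
    steps = [round(t / grid.delta_t) for t in times]
    xi = grid.xi
    C = initial_state(problem, grid)
    profiles: List[Profile] = []
    by_step = {}
    for s in steps:
        by_step.setdefault(s, []).append(s)
    if 0 in by_step:
        for _ in by_step[0]:
            profiles.append(Profile(t=0.0, coordinate="xi", grid=xi, values=C.copy()))
    last = max(steps) if steps else 0
    for step in range(1, last + 1):
        t_new = step * grid.delta_t
        system = assemble_step(problem, grid, t_new, C)
        C = thomas_solve(system)
        if not np.all(np.isfinite(C)):
            raise SolverError(f"non-finite state at step {step} (t = {t_new})")
        if step in by_step:
            for _ in by_step[step]:
                profiles.append(Profile(t=t_new, coordinate="xi", grid=xi,
                                        values=C.copy()))
    return profiles


@dataclass(frozen=True)
class GridIndependenceReport:
    """Result of comparing a solve against one with both steps halved."""

    base: FDGrid
    refined: FDGrid
    t_check: float
    sup_diff: float
    tolerance: float
    passed: bool


def grid_independence_check(problem: Problem, base: FDGrid, t_check: float,
                            tolerance: Optional[float] = None) -> GridIndependenceReport:
    """Solve at (dxi, dt) and (dxi/2, dt/2); compare at ``t_check``.

    The sup-norm difference is taken on the coarse nodes (a subset of the
    refined mesh).  Default tolerance is 1e-3 times the initial density
    scale.
    """
    if t_check <= 0:
        raise InputError(f"t_check must be > 0, got {t_check}")
    if tolerance is None:
        scale = problem.ic.C0 if problem.ic.kind == "step" else \
            float(np.max(np.abs(initial_state(problem, base))))
        tolerance = 1e-3 * scale
    refined = base.halved()
    coarse = solve_fd(problem, base, [t_check])[0]
    fine = solve_fd(problem, refined, [t_check])[0]
    diff = float(np.max(np.abs(coarse.values - fine.values[::2])))
    return GridIndependenceReport(base=base, refined=refined, t_check=float(t_check),
                                  sup_diff=diff, tolerance=float(tolerance),
                                  passed=diff <= tolerance)
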