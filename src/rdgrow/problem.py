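"""Problem statement types: initial conditions, full problems, profiles.

The governing conservation law on the growing domain 0 < x < L(t) is

    dC/dt = D d2C/dx2 - d(C v)/dx + k C,

with zero diffusive flux at both boundaries, where v(x, t) = x sigma(t) is
the growth velocity field, D > 0 the diffusivity and k the linear reaction
(production for k > 0, decay for k < 0) rate.  In the fixed coordinate
xi = x / L(t) this becomes

    dC/dt = (D / L^2(t)) d2C/dxi2 + (k - sigma(t)) C,

the form both the exact series and the finite-difference solver work with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .exceptions import InputError, ParameterError
from .growth import GrowthModel

__all__ = ["InitialCondition", "Problem", "Profile", "FourierCoefficients"]


@dataclass(frozen=True)
class InitialCondition:
    """Initial density profile on [0, L(0)].

    Two kinds are supported:

    ``step``
        C(x, 0) = C0 for 0 <= x < beta and 0 for beta <= x <= L(0): an
        initially colonized strip of width beta at density C0 next to the
        fixed end.  The value AT x = beta is 0 (half-open interval).
    ``general``
        an arbitrary integrable ``profile`` function x -> C(x, 0).
    """

    kind: str
    C0: Optional[float] = None
    beta: Optional[float] = None
    profile: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("step", "general"):
            raise ParameterError(f"unknown initial-condition kind {self.kind!r}")
        if self.kind == "step":
            if self.C0 is None or not (math.isfinite(self.C0) and self.C0 > 0):
                raise ParameterError(f"step IC requires C0 > 0, got {self.C0}")
            if self.beta is None or not (math.isfinite(self.beta) and self.beta > 0):
                raise ParameterError(f"step IC requires beta > 0, got {self.beta}")
        else:
            if self.profile is None:
                raise ParameterError("general IC requires a profile function")

    @classmethod
    def step(cls, C0: float, beta: float) -> "InitialCondition":
        return cls(kind="step", C0=C0, beta=beta)

    @classmethod
    def general(cls, profile: Callable[[float], float]) -> "InitialCondition":
        return cls(kind="general", profile=profile)

    def __call__(self, x, L0: float):
        """Evaluate C(x, 0); ``x`` may be a scalar or array."""
        x = np.asarray(x, dtype=float)
        if self.kind == "step":
            return np.where(x < self.beta, self.C0, 0.0)
        vals = np.vectorize(self.profile, otypes=[float])(x)
        if not np.all(np.isfinite(vals)):
            raise InputError("initial profile returned non-finite values")
        return vals


@dataclass(frozen=True)
class Problem:
    """Full problem statement: growth law, D, k and initial condition."""

    growth: GrowthModel
    D: float
    k: float
    ic: InitialCondition

    def __post_init__(self) -> None:
        if not (math.isfinite(self.D) and self.D > 0):
            raise ParameterError(f"diffusivity D must be > 0, got {self.D}")
        if not math.isfinite(self.k):
            raise ParameterError(f"reaction rate k must be finite, got {self.k}")
        if self.ic.kind == "step" and self.ic.beta > self.growth.L0 * (1 + 1e-12):
            raise ParameterError(
                f"step width beta = {self.ic.beta} exceeds L0 = {self.growth.L0}"
            )


@dataclass(frozen=True)
class Profile:
    """A density snapshot at time ``t``.

    ``coordinate`` is ``"x"`` (physical positions in [0, L(t)]) or ``"xi"``
    (fixed-domain positions in [0, 1]).  ``grid`` must be strictly
    increasing and the same length as ``values``.
    """

    t: float
    coordinate: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.coordinate not in ("x", "xi"):
            raise InputError(f"coordinate must be 'x' or 'xi', got {self.coordinate!r}")
        if self.grid.ndim != 1 or self.grid.size == 0:
            raise InputError("profile grid must be a non-empty 1-D array")
        if self.grid.shape != self.values.shape:
            raise InputError("grid and values must have the same length")
        if np.any(np.diff(self.grid) <= 0):
            raise InputError("profile grid must be strictly increasing")
        if self.coordinate == "xi" and (self.grid[0] < -1e-12 or self.grid[-1] > 1 + 1e-12):
            raise InputError("fixed-domain grid must lie within [0, 1]")

    def physical_grid(self, growth: GrowthModel) -> np.ndarray:
        """Positions in physical x, scaling a fixed-xi grid by L(t)."""
        if self.coordinate == "x":
            return self.grid
        return self.grid * growth.length(self.t)

    def to_physical(self, growth: GrowthModel) -> "Profile":
        """Return the same snapshot expressed on the physical grid."""
        if self.coordinate == "x":
            return self
        return Profile(t=self.t, coordinate="x",
                       grid=self.physical_grid(growth), values=self.values)


@dataclass(frozen=True)
class FourierCoefficients:
    """Cosine-series coefficients a_0 ... a_N of an initial profile on [0, L0].

    The represented profile is ``C(x, 0) = sum_n a_n cos(n pi x / L0)``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise InputError("coefficients must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise InputError("coefficients must be finite")

    @property
    def n_max(self) -> int:
        """Truncation order N (the highest cosine mode included)."""
        return self.values.size - 1

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, n):
        return self.values[n]
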