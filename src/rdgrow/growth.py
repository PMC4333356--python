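"""Uniform domain growth laws for 1-D reaction-diffusion problems.

A uniformly growing domain ``0 < x < L(t)`` stretches at the same relative
rate everywhere: the local velocity field is ``v(x, t) = x * sigma(t)`` with
``sigma(t) = L'(t) / L(t)``, so the origin stays fixed and the far boundary
moves at ``L'(t)``.  :class:`GrowthModel` encodes the length law ``L(t)``
together with the kinematic quantities derived from it, including the
rescaled (diffusive) time

    T(t) = integral_0^t D / L(s)^2 ds,

which maps the variable-coefficient diffusion problem on the growing domain
onto the constant-coefficient heat equation on the fixed interval [0, 1].
On growing domains T(t) saturates at a finite value as t -> infinity
(``D / (2 alpha L0^2)`` for exponential growth, ``D / (b L0)`` for linear
growth), while on a static domain T is unbounded -- the key structural
difference between the two settings.

Supported growth cases:

``static``
    L(t) = L0, sigma = 0.
``exponential``
    L(t) = L0 exp(alpha t), sigma = alpha (constant).
``linear``
    L(t) = L0 + b t, sigma = b / L(t).
``custom``
    any positive, non-decreasing user function t -> L(t); sigma and T are
    obtained by centered differencing of log L (relative step 1e-6) and
    adaptive quadrature of D / L^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

from scipy.integrate import quad
from scipy.optimize import brentq

from .exceptions import DomainError, ParameterError, RangeError

__all__ = ["GrowthModel", "GROWTH_CASES"]

GROWTH_CASES = ("static", "exponential", "linear", "custom")

#: relative step for the centered log-derivative of custom length laws
_CUSTOM_DIFF_STEP = 1e-6


def _check_time(t: float) -> float:
    t = float(t)
    if not math.isfinite(t) or t < 0.0:
        raise DomainError(f"time must be finite and >= 0, got {t}")
    return t


def _check_diffusivity(D: float) -> float:
    D = float(D)
    if not math.isfinite(D) or D <= 0.0:
        raise ParameterError(f"diffusivity D must be finite and > 0, got {D}")
    return D


@dataclass(frozen=True)
class GrowthModel:
    """Length law of a uniformly growing domain and its derived kinematics.

    Construct via the classmethods :meth:`static`, :meth:`exponential`,
    :meth:`linear` or :meth:`custom` rather than the raw constructor.

    Parameters
    ----------
    case
        One of ``"static"``, ``"exponential"``, ``"linear"``, ``"custom"``.
    L0
        Initial domain length L(0) > 0.
    alpha
        Exponential elongation rate (> 0); used iff ``case == "exponential"``.
    b
        Linear elongation speed (> 0); used iff ``case == "linear"``.
    custom_length
        Positive non-decreasing callable ``t -> L(t)``; used iff
        ``case == "custom"``.  Must satisfy ``custom_length(0) == L0``.
    """

    case: str
    L0: float
    alpha: Optional[float] = None
    b: Optional[float] = None
    custom_length: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.case not in GROWTH_CASES:
            raise ParameterError(
                f"unknown growth case {self.case!r}; expected one of {GROWTH_CASES}"
            )
        if not (math.isfinite(self.L0) and self.L0 > 0):
            raise ParameterError(f"L0 must be finite and > 0, got {self.L0}")
        if self.case == "exponential":
            if self.alpha is None or not (math.isfinite(self.alpha) and self.alpha > 0):
                raise ParameterError(
                    f"exponential growth requires alpha > 0, got {self.alpha}"
                )
        if self.case == "linear":
            if self.b is None or not (math.isfinite(self.b) and self.b > 0):
                raise ParameterError(f"linear growth requires b > 0, got {self.b}")
        if self.case == "custom":
            if self.custom_length is None:
                raise ParameterError("custom growth requires a length function")
            l0 = float(self.custom_length(0.0))
            if not math.isclose(l0, self.L0, rel_tol=1e-9):
                raise ParameterError(
                    f"custom length function has L(0) = {l0}, expected L0 = {self.L0}"
                )

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def static(cls, L0: float) -> "GrowthModel":
        """Non-growing domain, L(t) = L0."""
        return cls(case="static", L0=L0)

    @classmethod
    def exponential(cls, L0: float, alpha: float) -> "GrowthModel":
        """Exponentially elongating domain, L(t) = L0 exp(alpha t)."""
        return cls(case="exponential", L0=L0, alpha=alpha)

    @classmethod
    def linear(cls, L0: float, b: float) -> "GrowthModel":
        """Linearly elongating domain, L(t) = L0 + b t."""
        return cls(case="linear", L0=L0, b=b)

    @classmethod
    def custom(cls, L0: float, length: Callable[[float], float]) -> "GrowthModel":
        """User-supplied positive, non-decreasing length law."""
        return cls(case="custom", L0=L0, custom_length=length)

    # ------------------------------------------------------------------
    # kinematics
    # ------------------------------------------------------------------
    def length(self, t: float) -> float:
        """Domain length L(t); requires t >= 0."""
        t = _check_time(t)
        if self.case == "static":
            return self.L0
        if self.case == "exponential":
            return self.L0 * math.exp(self.alpha * t)
        if self.case == "linear":
            return self.L0 + self.b * t
        L = float(self.custom_length(t))
        if not (math.isfinite(L) and L > 0):
            raise ParameterError(f"custom length law returned non-positive L({t}) = {L}")
        return L

    def sigma(self, t: float) -> float:
        """Relative elongation rate sigma(t) = L'(t) / L(t)."""
        t = _check_time(t)
        if self.case == "static":
            return 0.0
        if self.case == "exponential":
            return self.alpha
        if self.case == "linear":
            return self.b / self.length(t)
        # custom: centered difference of log L, clipped at t = 0
        h = _CUSTOM_DIFF_STEP * max(t, 1.0)
        lo = max(t - h, 0.0)
        hi = t + h
        return (math.log(self.length(hi)) - math.log(self.length(lo))) / (hi - lo)

    def velocity(self, x: float, t: float) -> float:
        """Growth velocity field v(x, t) = x sigma(t); requires 0 <= x <= L(t)."""
        t = _check_time(t)
        x = float(x)
        L = self.length(t)
        if not (0.0 <= x <= L * (1.0 + 1e-12)):
            raise DomainError(f"position x = {x} outside the domain [0, {L}] at t = {t}")
        return x * self.sigma(t)

    # ------------------------------------------------------------------
    # rescaled (diffusive) time
    # ------------------------------------------------------------------
    def rescaled_time(self, D: float, t: float) -> float:
        """Rescaled time T(t) = int_0^t D / L(s)^2 ds (monotone increasing)."""
        D = _check_diffusivity(D)
        t = _check_time(t)
        if t == 0.0:
            return 0.0
        if self.case == "static":
            return D * t / self.L0**2
        if self.case == "exponential":
            return D * -math.expm1(-2.0 * self.alpha * t) / (2.0 * self.alpha * self.L0**2)
        if self.case == "linear":
            return D * t / (self.L0 * self.length(t))
        val, _err = quad(lambda s: D / self.length(s) ** 2, 0.0, t,
                         epsabs=1e-14, epsrel=1e-11, limit=200)
        return val

    def rescaled_time_limit(self, D: float) -> Optional[float]:
        """Limit of T(t) as t -> infinity.

        Returns ``math.inf`` for a static domain, the finite saturation value
        for exponential/linear growth, and ``None`` ("unknown") for a custom
        law, for which no closed form is attempted.
        """
        D = _check_diffusivity(D)
        if self.case == "static":
            return math.inf
        if self.case == "exponential":
            return D / (2.0 * self.alpha * self.L0**2)
        if self.case == "linear":
            return D / (self.b * self.L0)
        return None

    def invert_rescaled_time(self, D: float, T: float) -> float:
        """Inverse map t(T) of :meth:`rescaled_time`.

        For the three analytic cases the closed-form inverse is used; for a
        custom law the monotone map is inverted by bracketed Brent iteration
        (bracket doubled until it contains T, relative tolerance 1e-13).
        """
        D = _check_diffusivity(D)
        T = float(T)
        if T < 0.0:
            raise DomainError(f"rescaled time must be >= 0, got {T}")
        if T == 0.0:
            return 0.0
        limit = self.rescaled_time_limit(D)
        if limit is not None and T >= limit:
            raise RangeError(
                f"T = {T} is at or beyond the finite rescaled-time limit {limit} "
                f"of this {self.case} growth law"
            )
        if self.case == "static":
            return T * self.L0**2 / D
        if self.case == "exponential":
            return -math.log1p(-2.0 * self.alpha * self.L0**2 * T / D) / (2.0 * self.alpha)
        if self.case == "linear":
            return T * self.L0**2 / (D - T * self.L0 * self.b)
        # custom: double the bracket until it contains T, then Brent
        t_hi = 1.0
        while self.rescaled_time(D, t_hi) <= T:
            t_hi *= 2.0
            if t_hi > 1e12:
                raise RangeError(
                    f"T = {T} not reached by t = 1e12; the custom growth law may "
                    "have a finite rescaled-time limit below T"
                )
        return brentq(lambda s: self.rescaled_time(D, s) - T, 0.0, t_hi,
                      xtol=1e-14, rtol=1e-13)
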