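"""Scenario bundles: named parameter sets and config-file loading.

A :class:`Scenario` packs a full problem statement together with the
front-tracking threshold, series truncation, FD mesh and output times.  The
built-in scenarios are the worked parameter combinations of the reference
figures: an exponentially elongating domain (L0 = 1, alpha = 0.1, C0 = 1)
with diffusivity, initial colonized width and production rate varied one at
a time, plus static- and linear-growth demonstration cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .exceptions import ConfigError, ParameterError, RdgrowError
from .fd import FDGrid
from .growth import GrowthModel
from .problem import InitialCondition, Problem

__all__ = ["Scenario", "builtin_scenarios", "get_scenario", "load_scenario",
           "scenario_to_dict"]


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified computation."""

    name: str
    problem: Problem
    epsilon: float = 0.01
    n_max: int = 1000
    fd_grid: FDGrid = field(default_factory=FDGrid)
    output_times: Tuple[float, ...] = (0.0, 10.0, 20.0)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ParameterError(f"epsilon must be > 0, got {self.epsilon}")
        if self.n_max < 1:
            raise ParameterError(f"n_max must be >= 1, got {self.n_max}")
        if any(t < 0 for t in self.output_times) or \
                any(b <= a for a, b in zip(self.output_times, self.output_times[1:])):
            raise ParameterError("output_times must be strictly increasing and >= 0")


def _exp_scenario(name: str, D: float, k: float, beta: float) -> Scenario:
    problem = Problem(growth=GrowthModel.exponential(L0=1.0, alpha=0.1),
                      D=D, k=k, ic=InitialCondition.step(C0=1.0, beta=beta))
    return Scenario(name=name, problem=problem)


def builtin_scenarios() -> List[Scenario]:
    """The worked parameter combinations, plus static/linear demos.

    fig1a/fig1e/fig1i vary D in {1e-5, 1e-3, 1e-2} at k = 0.105, beta = 0.2;
    fig2a repeats fig1e; fig2e widens the initial condition to beta = 0.75;
    fig2i raises production to k = 1.705 (all at D = 1e-3).
    """
    scenarios = [
        _exp_scenario("fig1a", D=1e-5, k=0.105, beta=0.2),
        _exp_scenario("fig1e", D=1e-3, k=0.105, beta=0.2),
        _exp_scenario("fig1i", D=1e-2, k=0.105, beta=0.2),
        _exp_scenario("fig2a", D=1e-3, k=0.105, beta=0.2),
        _exp_scenario("fig2e", D=1e-3, k=0.105, beta=0.75),
        _exp_scenario("fig2i", D=1e-3, k=1.705, beta=0.2),
        Scenario(name="static-demo",
                 problem=Problem(growth=GrowthModel.static(L0=1.0), D=1e-3,
                                 k=0.105, ic=InitialCondition.step(C0=1.0, beta=0.2))),
        Scenario(name="linear-demo",
                 problem=Problem(growth=GrowthModel.linear(L0=1.0, b=0.05), D=1e-3,
                                 k=0.105, ic=InitialCondition.step(C0=1.0, beta=0.2))),
    ]
    return scenarios


def get_scenario(name: str) -> Scenario:
    """Look up a built-in scenario by name."""
    for s in builtin_scenarios():
        if s.name == name:
            return s
    names = ", ".join(s.name for s in builtin_scenarios())
    raise ConfigError(f"unknown scenario {name!r}; built-ins: {names}")


# ----------------------------------------------------------------------
# flat key-value config files
# ----------------------------------------------------------------------

_REQUIRED_KEYS = ("growth", "L0", "D", "k", "beta", "C0")
_OPTIONAL_KEYS = ("name", "alpha", "b", "epsilon", "n_max", "delta_xi",
                  "delta_t", "output_times")
_ALL_KEYS = set(_REQUIRED_KEYS) | set(_OPTIONAL_KEYS)


def _parse_kv(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, val = line.partition(sep)
                break
        else:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = key.strip(), val.strip()
        if key in out:
            raise ConfigError(f"line {lineno}: duplicate key {key!r}")
        out[key] = val
    return out


def _to_float(kv: Dict[str, str], key: str) -> float:
    try:
        return float(kv[key])
    except ValueError:
        raise ConfigError(f"key {key!r}: not a number: {kv[key]!r}") from None


def load_scenario(path) -> Scenario:
    """Read and validate a flat ``key = value`` (or ``key: value``) config.

    Required keys: growth (static|exponential|linear), L0, D, k, beta, C0.
    Optional: name, alpha (exponential), b (linear), epsilon, n_max,
    delta_xi, delta_t, output_times (comma-separated).  Unknown keys are
    rejected.
    """
    with open(path) as fh:
        kv = _parse_kv(fh.read())
    unknown = set(kv) - _ALL_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s): {', '.join(sorted(unknown))}")
    missing = [k for k in _REQUIRED_KEYS if k not in kv]
    if missing:
        raise ConfigError(f"missing required key(s): {', '.join(missing)}")

    growth_kind = kv["growth"]
    L0 = _to_float(kv, "L0")
    try:
        if growth_kind == "static":
            growth = GrowthModel.static(L0)
        elif growth_kind == "exponential":
            if "alpha" not in kv:
                raise ConfigError("key 'alpha' is required for exponential growth")
            growth = GrowthModel.exponential(L0, _to_float(kv, "alpha"))
        elif growth_kind == "linear":
            if "b" not in kv:
                raise ConfigError("key 'b' is required for linear growth")
            growth = GrowthModel.linear(L0, _to_float(kv, "b"))
        else:
            raise ConfigError(
                f"key 'growth': must be static, exponential or linear, got {growth_kind!r}")
        ic = InitialCondition.step(C0=_to_float(kv, "C0"), beta=_to_float(kv, "beta"))
        problem = Problem(growth=growth, D=_to_float(kv, "D"), k=_to_float(kv, "k"), ic=ic)
        fd_grid = FDGrid(delta_xi=_to_float(kv, "delta_xi") if "delta_xi" in kv else 0.001,
                         delta_t=_to_float(kv, "delta_t") if "delta_t" in kv else 0.001)
        output_times = tuple(
            float(s) for s in kv["output_times"].split(",")) if "output_times" in kv \
            else (0.0, 10.0, 20.0)
        return Scenario(
            name=kv.get("name", "config"),
            problem=problem,
            epsilon=_to_float(kv, "epsilon") if "epsilon" in kv else 0.01,
            n_max=int(_to_float(kv, "n_max")) if "n_max" in kv else 1000,
            fd_grid=fd_grid,
            output_times=output_times,
        )
    except ConfigError:
        raise
    except RdgrowError as exc:
        raise ConfigError(f"invalid scenario: {exc}") from exc


def scenario_to_dict(scenario: Scenario) -> Dict:
    """JSON-serializable echo of a scenario (for sidecar files)."""
    p = scenario.problem
    g = p.growth
    d = {
        "name": scenario.name,
        "growth": g.case,
        "L0": g.L0,
        "D": p.D,
        "k": p.k,
        "ic": {"kind": p.ic.kind, "C0": p.ic.C0, "beta": p.ic.beta},
        "epsilon": scenario.epsilon,
        "n_max": scenario.n_max,
        "delta_xi": scenario.fd_grid.delta_xi,
        "delta_t": scenario.fd_grid.delta_t,
        "output_times": list(scenario.output_times),
    }
    if g.alpha is not None:
        d["alpha"] = g.alpha
    if g.b is not None:
        d["b"] = g.b
    return d
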