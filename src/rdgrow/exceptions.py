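"""Exception hierarchy for rdgrow.

All rdgrow errors derive from :class:`RdgrowError` so callers (and the CLI)
can catch the package's failures with a single ``except`` clause.
"""


class RdgrowError(Exception):
    """Base class for all rdgrow errors."""


class DomainError(RdgrowError, ValueError):
    """An argument lies outside its mathematical domain (e.g. t < 0)."""


class ParameterError(RdgrowError, ValueError):
    """A model parameter violates its constraint (e.g. D <= 0, beta > L0)."""


class RangeError(RdgrowError, ValueError):
    """A requested value is beyond a finite attainable range."""


class UnsupportedCaseError(RdgrowError, ValueError):
    """The operation is defined only for specific growth cases."""


class OverflowGuardError(RdgrowError, OverflowError):
    """An exponential factor would overflow double precision."""


class SolverError(RdgrowError, RuntimeError):
    """The numerical solver failed (singular system, non-finite state)."""


class InputError(RdgrowError, ValueError):
    """Malformed user input (empty/unsorted grids, non-finite values)."""


class ConfigError(RdgrowError, ValueError):
    """A scenario configuration file is invalid."""
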