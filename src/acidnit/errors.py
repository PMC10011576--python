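"""Exception hierarchy shared across the package.

All validation failures raise subclasses of :class:`AcidnitError` so callers
can catch package-level problems without intercepting bare ``ValueError``.
"""


class AcidnitError(Exception):
    """Base class for all package errors."""


class UndefinedInputError(AcidnitError, ValueError):
    """An input makes the requested quantity mathematically undefined
    (e.g. zero tracer fraction, zero control rate, zero total pool)."""


class DegenerateIntervalError(AcidnitError, ValueError):
    """A rate was requested over an empty time interval (t1 <= t0)."""


class DomainError(AcidnitError, ValueError):
    """An input lies outside the physical domain an operation supports
    (e.g. temperature/salinity outside the range of the fitted constants)."""


class NoSolutionError(AcidnitError, RuntimeError):
    """A root-finder could not bracket a solution; the result is reported
    as unsolvable rather than guessed."""


class DegenerateMixingError(AcidnitError, ValueError):
    """Two-endmember mixing requested with identical endmembers."""


class SchemaError(AcidnitError, ValueError):
    """Tabular input does not conform to the expected column schema or
    contains values that violate a type invariant."""
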