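"""Exception hierarchy.

Every error raised by ternacoop derives from :class:`TernacoopError`, with a
machine-parsable ``error_class`` attribute used by the CLI for exit reporting.
"""

from __future__ import annotations


class TernacoopError(Exception):
    """Base class for all ternacoop errors."""

    error_class = "error"


class InvalidParameterError(TernacoopError, ValueError):
    """A scalar input violates its domain (negative concentration, Kd <= 0, ...)."""

    error_class = "invalid-parameter"


class SolverFailureError(TernacoopError, RuntimeError):
    """The free-ligand root solve could not bracket or converge."""

    error_class = "solver-failure"


class InternalConsistencyError(TernacoopError, RuntimeError):
    """The closed-form discriminant went negative beyond rounding."""

    error_class = "internal-consistency"


class UndefinedFractionError(TernacoopError, ZeroDivisionError):
    """Ternary fraction requested with a zero limiting species."""

    error_class = "undefined-fraction"


class InsufficientRangeError(TernacoopError, ValueError):
    """A titration grid does not span the region a quantity is defined on."""

    error_class = "insufficient-range"


class SchemaError(TernacoopError, ValueError):
    """A frame-energy table violates the required schema."""

    error_class = "schema-error"


class InsufficientDataError(TernacoopError, ValueError):
    """Too few matched records for a statistical comparison."""

    error_class = "insufficient-data"


class IncompleteLedgerError(TernacoopError, ValueError):
    """A free-energy ledger is missing required components."""

    error_class = "incomplete-ledger"


class UnitParseError(TernacoopError, ValueError):
    """A quantity string could not be parsed into canonical units."""

    error_class = "parse-error"


class IOErrorClass(TernacoopError, OSError):
    """A required input file is missing or unreadable."""

    error_class = "io-error"
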