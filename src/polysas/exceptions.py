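"""Exception hierarchy shared across the package."""


class PolysasError(Exception):
    """Base class for all package-specific errors."""


class InvalidGridError(PolysasError, ValueError):
    """A q or parameter grid violates its invariants."""


class ShapeError(PolysasError, ValueError):
    """Array shapes are inconsistent with the declared grids."""


class DomainError(PolysasError, ValueError):
    """A scalar argument lies outside its physical domain."""


class DataError(PolysasError, ValueError):
    """Observed intensity data violate their invariants."""


class ConfigurationError(PolysasError, ValueError):
    """A configuration file or block is invalid."""


class ParseError(PolysasError, ValueError):
    """A data file could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MemoryBudgetError(PolysasError, MemoryError):
    """A requested tensor exceeds the configured in-core memory budget.

    Attributes
    ----------
    estimated_bytes : int
        Size the dense tensor would occupy in double precision.
    """

    def __init__(self, message: str, estimated_bytes: int):
        self.estimated_bytes = estimated_bytes
        super().__init__(message)


class DegenerateStateError(PolysasError, ValueError):
    """A slack vector has (numerically) zero norm and cannot be decoded."""


class SolverError(PolysasError, RuntimeError):
    """The inverse solver failed in a way that yields no usable state."""
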