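"""Exception hierarchy shared across fermkin modules."""


class FermkinError(Exception):
    """Base class for all fermkin-specific errors."""


class DomainError(FermkinError, ValueError):
    """Input outside the mathematical domain of an operation."""


class DegenerateDataError(FermkinError, ValueError):
    """Data carries no usable signal (e.g. constant series, zero variance)."""


class InsufficientDataError(FermkinError, ValueError):
    """Fewer observations than free parameters."""


class SelectionError(FermkinError, RuntimeError):
    """No candidate model could be fitted successfully."""


class ParseError(FermkinError, ValueError):
    """A delimited-text input failed to parse.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(FermkinError, ValueError):
    """Invalid run or simulation configuration."""
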