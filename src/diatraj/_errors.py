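"""Exception hierarchy shared across the pipeline stages."""


class DiatrajError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DiatrajError):
    """A configuration value is invalid; the message names the field."""


class DomainError(DiatrajError, ValueError):
    """A numeric input lies outside the mathematical domain of an operation."""


class ContractError(DiatrajError):
    """A precondition between pipeline stages was violated."""


class SchemaError(DiatrajError):
    """A file does not match its documented schema."""


class ParseError(DiatrajError):
    """A delimited input file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FittingError(DiatrajError):
    """Model or centroid fitting failed on valid-looking input."""


class ModelError(DiatrajError):
    """The fixed-effects design is unusable (e.g. aliased columns)."""
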