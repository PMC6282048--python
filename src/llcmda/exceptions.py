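"""Exception hierarchy shared across the package."""


class LLCMDAError(Exception):
    """Base class for all package errors."""


class ValidationError(LLCMDAError, ValueError):
    """Input violates a documented invariant or precondition."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ShapeError(ValidationError):
    """A matrix has the wrong shape for the requested operation."""


class LabelAlignmentError(ValidationError):
    """Two labeled containers disagree on entity labels or their order."""


class ConfigError(ValidationError):
    """A configuration value is out of its admissible range."""


class NumericalError(LLCMDAError, RuntimeError):
    """A numerical procedure failed (singular system, divergence, ...)."""
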