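"""Exception hierarchy shared across the package."""


class OursenseError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OursenseError, ValueError):
    """Raised when an input violates a documented precondition."""


class ParseError(OursenseError, ValueError):
    """Raised when a file cannot be parsed; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DegenerateFitError(OursenseError, RuntimeError):
    """Raised when an identification problem is singular or rank deficient."""


class InvalidModelError(OursenseError, ValueError):
    """Raised when fitted model coefficients are unusable (e.g. non-positive root)."""


class DataQualityWarning(UserWarning):
    """Non-fatal anomaly in a sensor stream (decreasing cOUR, floored estimate)."""
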