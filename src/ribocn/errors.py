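"""Exception hierarchy shared across the package."""


class RibocnError(Exception):
    """Base class for all package errors."""


class CoordinateError(RibocnError, ValueError):
    """A genomic coordinate falls outside the sequence or interval it addresses."""


class ValidationError(RibocnError, ValueError):
    """An input value violates a documented precondition."""


class ParseError(RibocnError, ValueError):
    """A text input (BED/TSV) could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EstimationError(RibocnError, ValueError):
    """A per-sample estimate could not be computed (e.g. zero read baseline)."""


class InsufficientDataError(RibocnError, ValueError):
    """Too few observations to compute the requested statistic."""


class ModelError(RibocnError, ValueError):
    """A regression model could not be fit (rank deficiency, separation...)."""


class ConfigurationError(RibocnError, ValueError):
    """A required configuration entry is missing or inconsistent."""
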