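"""Exception hierarchy for the pipeline."""


class TsaquantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsaquantError):
    """An invalid configuration value; the message names the field."""


class ValidationError(TsaquantError):
    """Input data violates a precondition (bad characters, bad lengths...)."""


class CoordinateError(TsaquantError):
    """A feature lies outside the coordinate system it is addressed in."""


class AnnotationError(TsaquantError):
    """An annotation (e.g. a CDS) is missing or inconsistent."""


class ParseError(TsaquantError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
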