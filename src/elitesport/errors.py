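"""Exception and warning types shared across the pipeline."""


class EliteSportError(Exception):
    """Base class for all package errors."""


class ValidationError(EliteSportError):
    """Invalid configuration or input data (CLI exit code 1)."""


class NormCoverageError(ValidationError):
    """A required (measurement, group) cell is missing from the norm table."""


class SeparationError(EliteSportError):
    """Complete or quasi-complete separation detected in a logistic fit."""

    def __init__(self, term: str, message: str | None = None):
        self.term = term
        super().__init__(message or f"separation detected on term {term!r}")


class DegenerateGroupWarning(UserWarning):
    """A standardization group is a singleton or has zero variance; z set to 0."""
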