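"""Exception hierarchy for the stepselect pipeline.

Every stage raises a subclass of :class:`StepSelectError` so callers (and the
CLI) can halt with the stage name and the offending entity.
"""


class StepSelectError(Exception):
    """Base class for all stepselect errors."""


class ConfigurationError(StepSelectError):
    """Invalid configuration value (fractions not summing to 1, k < 1, ...)."""


class SchemaError(StepSelectError):
    """A landscape feature class is unknown or the schema is malformed."""


class DomainError(StepSelectError):
    """A point or start location lies outside the raster extent."""


class InsufficientDataError(StepSelectError):
    """Too few fixes/steps to perform the requested operation."""


class FormatError(StepSelectError):
    """A file violates its declared schema (missing column, duplicate key...)."""


class DesignError(StepSelectError):
    """A case-control design has no estimable terms or broken strata."""


class SeparationError(StepSelectError):
    """Complete/quasi-complete separation: the partial likelihood is unbounded."""

    def __init__(self, term: str, message: str | None = None):
        self.term = term
        super().__init__(message or f"separation detected for term {term!r}")
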