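"""Exception hierarchy shared across the package."""


class LamigainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LamigainError):
    """A file does not conform to the expected on-disk schema."""


class IntegrityError(LamigainError):
    """Data violate an invariant of the trial-response data model."""


class AnalysisValidationError(LamigainError, ValueError):
    """Inputs are outside the domain of an analysis operation."""


class UndefinedStatisticError(LamigainError):
    """A statistic is mathematically undefined for the given input
    (e.g. zero blank variance, zero DSI denominator)."""


class FitError(LamigainError):
    """A model fit could not be carried out (underdetermined, degenerate)."""
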