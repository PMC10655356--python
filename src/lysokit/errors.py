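"""Exception hierarchy shared across the package."""


class LysokitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LysokitError):
    """An input table is malformed (e.g. a required column is missing)."""


class EmptyInputError(LysokitError):
    """An input table or record list is empty where data are required."""


class ValidationError(LysokitError):
    """A value violates a documented precondition (negative intensity, p outside [0,1], ...)."""


class ConfigError(LysokitError):
    """Invalid or conflicting configuration."""


class InsufficientDataError(LysokitError):
    """Too few observations to run the requested computation."""


class InsufficientOverlapError(LysokitError):
    """Two result sets share too few subjects to be compared."""


class NormalizationError(LysokitError):
    """The reference protein is missing or non-positive in at least one sample."""


class AlignmentError(LysokitError):
    """Result tables that must share a protein universe do not overlap."""


class DesignError(LysokitError):
    """An experimental-design requirement is violated (e.g. <2 samples per group)."""


class MonotonicityError(LysokitError):
    """A fitted calibration curve is not strictly monotone over its valid range."""
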