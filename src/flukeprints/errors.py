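"""Exception hierarchy shared across the package."""


class FlukeprintError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(FlukeprintError, ValueError):
    """Raised when an input value violates a precondition (non-finite, nonpositive, ...)."""


class InsufficientDataError(InvalidInputError):
    """Raised when too few observations are available for an estimate."""


class GeometryError(FlukeprintError):
    """Raised for unsupported viewing geometry (e.g. oblique frames)."""


class InvalidDesignError(FlukeprintError):
    """Raised when a statistical design cannot be fitted (e.g. a single class
    supplied to a between-class analysis)."""


class DegenerateFitError(FlukeprintError):
    """Raised when a fit is undefined for the supplied data (e.g. zero covariance)."""


class UndefinedBearingError(InvalidInputError):
    """Raised when a compass bearing is requested between coincident points."""


class SchemaError(FlukeprintError):
    """Raised when an annotation table does not conform to the expected schema."""
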