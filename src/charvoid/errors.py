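"""Exception hierarchy shared by all pipeline stages."""


class CharvoidError(Exception):
    """Base class for all package errors."""


class ValidationError(CharvoidError, ValueError):
    """A parameter or argument violates a documented precondition."""


class GeometryError(CharvoidError):
    """The requested geometry does not fit the voxel grid."""


class DataError(CharvoidError):
    """Input data violate an assumption (e.g. flat field below dark field)."""


class NoSeedFound(CharvoidError):
    """Segmentation found no foreground object."""


class DegenerateDataError(CharvoidError):
    """A statistical test cannot be computed (e.g. zero within-group variance)."""


class FormatError(CharvoidError):
    """A file could not be parsed as the expected container format."""
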