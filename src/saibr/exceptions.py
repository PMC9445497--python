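"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`SaibrError`,
so callers can catch one type at a batch boundary while letting genuine bugs
(TypeError, OSError from unreadable files, ...) propagate.
"""


class SaibrError(Exception):
    """Base class for all errors raised by saibr."""


class ChannelGeometryError(SaibrError):
    """Channel images and/or the ROI mask do not share a single shape."""


class DataError(SaibrError):
    """Pixel data violates a basic contract (non-finite values, empty ROI)."""


class ConfigurationError(SaibrError):
    """A required input (channel, background frame, model mode) is missing or
    inconsistent with the requested operation."""


class ParameterError(SaibrError, ValueError):
    """A scalar parameter is out of its valid range."""


class InsufficientDataError(SaibrError):
    """Too few observations for the requested fit."""


class DegeneratePredictorError(SaibrError):
    """A predictor has zero variance, so no slope is identifiable."""


class CollinearityError(SaibrError):
    """The multi-predictor design matrix is rank deficient."""


class SpilloverError(SaibrError):
    """The spillover-compensated solution does not exist (m*s >= 1)."""


class ModelSchemaError(SaibrError):
    """A serialized calibration model is missing required fields."""


class ModelVersionError(SaibrError):
    """A serialized calibration model declares an unsupported schema version."""


class GeometryError(SaibrError):
    """A contour or profile geometry is unusable (e.g. entirely off-image)."""
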