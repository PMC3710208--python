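"""Exception hierarchy.

Every error raised by the library derives from :class:`GelCorrError` so
callers can catch the whole family at pipeline boundaries.
"""


class GelCorrError(Exception):
    """Base class for all gelcorr errors."""


class ManifestError(GelCorrError):
    """Manifest schema violation (missing column, duplicate sample id, bad flag)."""


class ImageLoadError(GelCorrError):
    """An image file could not be read or has an unsupported layout."""


class DimensionMismatchError(GelCorrError):
    """Images in one stack do not share a common height x width."""


class EncodingError(GelCorrError):
    """An external variable could not be encoded numerically."""


class ParameterError(GelCorrError):
    """Invalid transform or configuration parameter."""


class EstimationError(GelCorrError):
    """Landmark-based transform estimation is degenerate."""


class DegenerateImageError(GelCorrError):
    """Normalization scale statistic is zero (or sigma is zero for z-score)."""


class UndefinedCorrelationError(GelCorrError):
    """Correlation undefined: constant vector or too few samples."""


class InsufficientSamplesError(GelCorrError):
    """Too few samples for the requested statistical test."""


class UnknownMapError(GelCorrError):
    """A named result map or product factor does not exist."""


class RoiError(GelCorrError):
    """Region of interest falls outside the map bounds."""


class StageError(GelCorrError):
    """Pipeline-stage failure; message is tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
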