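"""Exception hierarchy shared across the toolkit."""


class HerdmotionError(Exception):
    """Base class for all herdmotion errors."""


class InvalidGeometryError(HerdmotionError):
    """Degenerate polygon: fewer than 3 distinct vertices or zero area."""


class EmptyMaskError(HerdmotionError):
    """A rasterized contour covered no pixel inside the frame (m00 = 0)."""


class ConvergenceError(HerdmotionError):
    """Iterative solver exhausted its iteration budget.

    Carries the last iterate so callers can inspect how far it got.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class FormatError(HerdmotionError):
    """Malformed segmentation-label line or record."""


class ManifestError(HerdmotionError):
    """Inconsistent frame manifest (duplicates, ordering, bad timestamps)."""


class ParameterError(HerdmotionError):
    """Invalid argument value (bad enum, out-of-range count, ...)."""


class OrderingError(HerdmotionError):
    """A sequence required to be chronological is not."""


class ReportError(HerdmotionError):
    """A report artifact is missing or unusable."""
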