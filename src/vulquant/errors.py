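"""Exception hierarchy for the quantification pipeline."""


class VulquantError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(VulquantError):
    """Physical calibration (voxel size) is missing or invalid."""


class FormatError(VulquantError):
    """An image file is not a supported grayscale multi-page TIFF."""


class SegmentationError(VulquantError):
    """Thresholding failed to produce a usable cell/nucleus mask."""

    def __init__(self, message: str, threshold: float | None = None):
        super().__init__(message)
        self.threshold = threshold


class UndefinedIndexError(VulquantError):
    """A polarity index is undefined (a half-compartment is empty)."""


class InfiniteIndexError(VulquantError):
    """A polarity index denominator (dorsal/distal mean) is zero."""


class GeometryError(VulquantError):
    """Annotation geometry is missing or inconsistent."""


class DegenerateInputError(VulquantError):
    """A statistical routine received input it cannot operate on."""
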