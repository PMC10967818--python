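"""Exception hierarchy for opdcyto."""


class OpdCytoError(Exception):
    """Base class for all opdcyto errors."""


class RasterTooSmallError(OpdCytoError):
    """The requested raster cannot contain the cell (plus margins)."""


class InconsistentMorphologyError(OpdCytoError):
    """Cell class and morphology parameters contradict each other."""


class CarrierNotFoundError(OpdCytoError):
    """No distinct carrier-fringe peak in the Fourier spectrum."""


class OrderOverlapError(OpdCytoError):
    """Fourier window geometry would mix diffraction orders."""


class NoCellFoundError(OpdCytoError):
    """No pixel above the segmentation threshold."""


class InsufficientBackgroundError(OpdCytoError):
    """Too few background pixels to fit a reference surface."""


class DegenerateSeparationError(OpdCytoError):
    """The two samples are identical; no separating threshold exists."""


class OrderViolationError(OpdCytoError):
    """Class means violate the assumed ordering (mean H < mean L)."""
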