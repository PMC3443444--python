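"""Exception hierarchy.

Every failure mode of the pipeline maps onto one of these so callers (and
the batch driver) can distinguish bad inputs from algorithmic failures.
"""


class OCTGraftError(Exception):
    """Base class for all package errors."""


class ImageFormatError(OCTGraftError):
    """Input image is not a readable grayscale 8/16-bit PNG/TIFF."""


class ParameterError(OCTGraftError, ValueError):
    """An algorithm parameter is out of its valid range."""


class ConfigError(OCTGraftError):
    """Run configuration failed validation (unknown key, bad value)."""


class SegmentationFormatError(OCTGraftError):
    """A serialized segmentation record could not be parsed."""


class PhantomSpecError(OCTGraftError):
    """A phantom specification is geometrically infeasible."""


class EmptyBoundaryError(OCTGraftError):
    """No edge pixels found in the requested band."""


class CornerDetectionError(OCTGraftError):
    """Fewer significant curvature maxima than needed to place 4 corners."""


class LowContrastError(OCTGraftError):
    """Host-graft interface undetectable in too many columns (thin-graft
    regime: the interface has too little contrast with its surroundings)."""


class GeometryError(OCTGraftError):
    """A segmentation violates a geometric invariant (negative thickness,
    self-intersecting outline, degenerate lateral span)."""


class DegenerateDataError(OCTGraftError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
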