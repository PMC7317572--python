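"""Exception types raised across the pipeline."""


class Panicle3DError(Exception):
    """Base class for all pipeline errors."""


class FormatError(Panicle3DError):
    """Unreadable or unsupported volume file."""


class DimensionError(Panicle3DError):
    """Inconsistent slice shapes in a stack."""


class StandardizationError(Panicle3DError):
    """Intensity histogram has no distinguishable air peak."""


class CropError(Panicle3DError):
    """Requested crop would leave an empty volume."""


class SegmentationError(Panicle3DError):
    """Thresholding produced no foreground."""


class HullError(Panicle3DError):
    """Convex hull of a degenerate (coplanar/collinear) voxel set."""


class EllipsoidFitError(Panicle3DError):
    """Degenerate covariance; no ellipsoid can be fitted."""


class StemError(Panicle3DError):
    """Skeleton's thick region is disconnected bottom-to-top."""


class AlignmentError(Panicle3DError):
    """Mismatched accession labels between matrices or tables."""
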