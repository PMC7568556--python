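"""Exception hierarchy shared across the pipeline."""


class DungscoreError(Exception):
    """Base class for all package errors."""


class RigConfigError(DungscoreError):
    """Light-rig configuration is invalid (count, norm, band or rank)."""


class IllPosedError(RigConfigError):
    """The 3xN light-direction matrix has rank < 3; PS inversion is ill-posed."""


class ImageFormatError(DungscoreError):
    """Input images cannot be decoded or do not share dimensions."""


class DegenerateHistogramError(DungscoreError):
    """Otsu thresholding received a constant image."""


class SegmentationError(DungscoreError):
    """Mask extraction produced an empty foreground."""


class DegenerateMaskError(DungscoreError):
    """Mask has too few / collinear pixels for a convex hull."""


class EmptyMaskError(DungscoreError):
    """A metric was asked to average over an empty mask."""


class NormalisationError(DungscoreError):
    """A metric is zero across the whole batch and cannot be scaled to max 1."""


class SyntheticSpecError(DungscoreError):
    """Synthetic-sample parameters are inconsistent (e.g. outline radius <= 0)."""


class UnsupportedMethodError(DungscoreError):
    """Requested image-combination method is not allowed (e.g. max)."""


class ManifestError(DungscoreError):
    """Sample manifest is malformed or inconsistent with its rigs."""


class ClassifierError(DungscoreError):
    """Patch classifier used before fitting, or with inconsistent inputs."""
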