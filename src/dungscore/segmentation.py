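"""Sample segmentation: Otsu threshold on the minimum image plus clean-up.

The sample sits on ground that appears *lighter* than the sample itself, so
foreground pixels are those at or below an automatically chosen threshold.
Thresholding uses the per-pixel minimum over the light stack, I_min, which
suppresses specular highlights (a highlight rarely appears under more than
one light) and avoids bias toward any single illumination direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import DegenerateHistogramError, SegmentationError
from .photometric import ImageStack

#: 4-connectivity structuring element used for all component labelling
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Clean-up configuration.

    erosion_radius is in pixels at the native ~4 MP capture resolution;
    multiply by ``scale`` for smaller frames (scaled radius is rounded, with
    0 meaning no erosion).
    """

    erosion_radius: int = 5
    otsu_bins: int = 256
    min_foreground_frac: float = 0.01
    max_foreground_frac: float = 0.9
    scale: float = 1.0

    @property
    def effective_erosion_radius(self) -> int:
        return int(round(self.erosion_radius * self.scale))


@dataclass(frozen=True)
class SampleMask:
    """Binary mask, 1 = sample pixel; single 4-connected component, hole-free."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def min_image(stack: ImageStack) -> np.ndarray:
    """Per-pixel minimum intensity across the stack (I_min)."""
    return stack.images.min(axis=0)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Bin-edge threshold maximising between-class variance; lowest tie wins.

    The image is histogrammed over [0, 1] into ``n_bins`` bins; for each
    candidate split the between-class variance w0*w1*(mu0 - mu1)^2 is
    computed from exact per-bin intensity sums (not bin centres).  The
    returned value is the upper edge of the last foreground bin, so
    ``image <= threshold`` reproduces the optimal partition.
    """
    vals = np.asarray(image, dtype=float).ravel()
    if vals.max() == vals.min():
        raise DegenerateHistogramError("constant image: Otsu threshold undefined")
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    sums, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0), weights=vals)
    w0 = np.cumsum(counts)[:-1].astype(float)
    s0 = np.cumsum(sums)[:-1]
    w1 = vals.size - w0
    s1 = sums.sum() - s0
    valid = (w0 > 0) & (w1 > 0)
    bcv = np.full(n_bins - 1, -np.inf)
    m0 = np.divide(s0, w0, out=np.zeros_like(s0), where=valid)
    m1 = np.divide(s1, w1, out=np.zeros_like(s1), where=valid)
    bcv[valid] = w0[valid] * w1[valid] * (m0[valid] - m1[valid]) ** 2
    k = int(np.argmax(bcv))  # argmax returns the first (lowest) maximiser
    return float(edges[k + 1])


def extract_mask(stack: ImageStack, params: SegmentationParams | None = None) -> SampleMask:
    """Segment the sample from I_min: Otsu -> fill -> erode -> largest component -> fill.

    The final fill guarantees the hole-free invariant; keeping only the
    largest 4-connected component removes splatter satellites and bright-spot
    artefacts.  Raises :class:`SegmentationError` if nothing survives.
    """
    params = params or SegmentationParams()
    imin = min_image(stack)
    threshold = otsu_threshold(imin, params.otsu_bins)
    fg = imin <= threshold
    frac = fg.mean()
    if not (params.min_foreground_frac < frac < params.max_foreground_frac):
        warnings.warn(
            f"foreground fraction {frac:.3f} outside "
            f"({params.min_foreground_frac}, {params.max_foreground_frac}); "
            "the darker-sample-on-lighter-ground assumption may be violated",
            stacklevel=2,
        )
    fg = ndimage.binary_fill_holes(fg)
    r = params.effective_erosion_radius
    if r > 0:
        fg = ndimage.binary_erosion(fg, structure=disk(r))
    labels, n_lab = ndimage.label(fg, structure=FOUR_CONNECTED)
    if n_lab == 0:
        raise SegmentationError("empty foreground after morphological clean-up")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return SampleMask(mask=fg)
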