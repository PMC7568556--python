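"""Consistency metrics and the combined score.

Three per-sample metrics quantify how a dropped faecal sample looks:

* **border** S_B = 1 - solidity of the segmented mask (solidity = mask area /
  convex-hull area).  Runny samples splatter, giving ragged borders, low
  solidity and high S_B.
* **shininess** S_S = mean over the mask of I' = I_max - I_min, the per-pixel
  spread of intensity across the light stack.  A specular highlight appears
  under (at most) one light, so wet shiny samples have large I'.
* **normal** S_N = mean over the mask of a texture-roughness image built from
  the z-component of the surface normals: high-pass N' = |GF(N) - N|
  (Gaussian, sigma 5 px), denoise with a centre-weighted local median, then a
  local standard-deviation filter over a radius-51 px disc.  Firm samples
  have rough 3-D topography and score high.

Within a batch each metric is divided by its batch maximum so the best score
is 1, then the total is

    S = S_N / (S_B * S_S^2)

(the squared shininess weighting was found to separate samples better than
the plain S_N / (S_B * S_S), which remains available via ``squared=False``).
High S means firm: rough surface, matte, compact border.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from skimage.morphology import convex_hull_image

from .errors import DegenerateMaskError, DungscoreError, EmptyMaskError, NormalisationError
from .photometric import ImageStack, SurfaceMap, solve_ps
from .segmentation import SampleMask, SegmentationParams, extract_mask

logger = logging.getLogger(__name__)

#: default metric-to-band assignment; single-band input falls back to that band
DEFAULT_BAND_ASSIGNMENT: Mapping[str, str] = {
    "border": "VIS",
    "shininess": "VIS",
    "normal": "NIR",
}


@dataclass(frozen=True)
class FilterParams:
    """Normal-metric filter configuration, in pixels at ~4 MP resolution.

    ``scale`` adapts the resolution-bound sizes to other frame sizes: the
    Gaussian sigma and the SDF radius are multiplied by it.  The weighted
    median neighbourhood is *not* scaled: it is a small denoising primitive
    whose job is rejecting pixel-scale highlight speckle, and shrinking it
    below speckle-rejection size defeats it.  ``epsilon`` guards the total
    score's division against zero metrics.
    """

    gaussian_sigma: float = 5.0
    median_neighbourhood: int = 20  # neighbours around the centre pixel
    median_centre_weight: int = 3
    sdf_radius: int = 51
    epsilon: float = 1e-6
    scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gaussian_sigma, self.median_neighbourhood, self.sdf_radius,
               self.epsilon, self.scale) <= 0:
            raise ValueError("all FilterParams fields must be strictly positive")

    @property
    def effective_sigma(self) -> float:
        return self.gaussian_sigma * self.scale

    @property
    def effective_sdf_radius(self) -> int:
        return max(1, int(round(self.sdf_radius * self.scale)))

    @property
    def effective_median_neighbourhood(self) -> int:
        return self.median_neighbourhood


@dataclass(frozen=True)
class MetricSet:
    """Raw and batch-normalised metrics plus total score for one sample."""

    sample_id: str
    border_raw: float
    shininess_raw: float
    normal_raw: float
    border: float | None = None
    shininess: float | None = None
    normal: float | None = None
    total: float | None = None
    rank: int | None = None


def border_metric(mask: SampleMask) -> float:
    """S_B = 1 - solidity; 0 for convex shapes, toward 1 for ragged splatter."""
    m = mask.mask
    if m.sum() < 3:
        raise DegenerateMaskError("mask needs >= 3 pixels for a convex hull")
    coords = np.argwhere(m)
    if np.linalg.matrix_rank(coords - coords.mean(axis=0)) < 2:
        raise DegenerateMaskError("mask pixels are collinear; hull has no area")
    hull = convex_hull_image(m)
    return float(1.0 - m.sum() / hull.sum())


def shininess_metric(stack: ImageStack, mask: SampleMask) -> float:
    """Mean of I' = I_max - I_min over mask pixels; in [0, 1]."""
    if mask.area == 0:
        raise EmptyMaskError("shininess metric over an empty mask")
    iprime = stack.images.max(axis=0) - stack.images.min(axis=0)
    return float(iprime[mask.mask].mean())


def _median_offsets(n_neighbours: int) -> list[tuple[int, int]]:
    """Centre pixel plus its n nearest offsets by Euclidean distance (deterministic)."""
    r = int(np.ceil(np.sqrt(n_neighbours))) + 1
    offs = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if (dy, dx) != (0, 0)
    ]
    offs.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2, o[0], o[1]))
    return [(0, 0)] + offs[:n_neighbours]


def weighted_median_filter(
    image: np.ndarray, n_neighbours: int = 20, centre_weight: int = 3
) -> np.ndarray:
    """Local median over the centre pixel + its n nearest neighbours.

    The centre is replicated ``centre_weight`` times before taking the
    median, giving it higher weight; boundaries use reflect padding.
    """
    offsets = _median_offsets(n_neighbours)
    pad = max(max(abs(dy), abs(dx)) for dy, dx in offsets)
    h, w = image.shape
    padded = np.pad(image, pad, mode="reflect")
    layers = [
        padded[pad + dy : pad + dy + h, pad + dx : pad + dx + w] for dy, dx in offsets
    ]
    layers.extend([image] * (centre_weight - 1))
    return np.median(np.stack(layers, axis=-1), axis=-1)


def local_std_filter(image: np.ndarray, radius: int) -> np.ndarray:
    """Sample standard deviation (n-1 denominator) over a circular window.

    The disc is rasterised by centre distance <= radius; boundaries use
    reflect padding.  FFT convolution keeps this tractable for large radii.
    """
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    foot = (yy**2 + xx**2 <= radius**2).astype(float)
    n = foot.sum()
    padded = np.pad(np.asarray(image, dtype=float), radius, mode="reflect")
    s1 = fftconvolve(padded, foot, mode="valid")
    s2 = fftconvolve(padded**2, foot, mode="valid")
    var = np.maximum(s2 - s1**2 / n, 0.0) / (n - 1)
    return np.sqrt(var)


def normal_metric(
    surface: SurfaceMap | np.ndarray,
    mask: SampleMask,
    params: FilterParams | None = None,
) -> float:
    """Roughness of the n_z field: high-pass, weighted median, local std, mean.

    Accepts a :class:`SurfaceMap` or a bare (H, W) n_z array.  All filters
    run on the full frame; the mask is applied only at the final mean.
    """
    params = params or FilterParams()
    nz = surface.nz if isinstance(surface, SurfaceMap) else np.asarray(surface, dtype=float)
    if nz.shape != mask.mask.shape:
        raise DungscoreError(f"normal field {nz.shape} vs mask {mask.mask.shape}")
    if mask.area == 0:
        raise EmptyMaskError("normal metric over an empty mask")
    nprime = np.abs(gaussian_filter(nz, params.effective_sigma, mode="reflect") - nz)
    smoothed = weighted_median_filter(
        nprime, params.effective_median_neighbourhood, params.median_centre_weight
    )
    ndouble = local_std_filter(smoothed, params.effective_sdf_radius)
    return float(ndouble[mask.mask].mean())


def normalise_batch(raw_metrics: Sequence[MetricSet]) -> list[MetricSet]:
    """Scale each metric by its batch maximum so every metric's best value is 1.

    Raw values are retained alongside.  Idempotent: renormalising a
    normalised batch changes nothing.
    """
    if not raw_metrics:
        raise NormalisationError("empty batch")
    out = []
    maxima = {}
    for name in ("border", "shininess", "normal"):
        mx = max(getattr(m, f"{name}_raw") for m in raw_metrics)
        if mx <= 0:
            raise NormalisationError(f"metric '{name}' is zero across the whole batch")
        maxima[name] = mx
    if len(raw_metrics) == 1:
        warnings.warn(
            "normalising a single-sample batch: all metrics become 1 and the "
            "total score is 1 by construction; compare raw values across batches",
            stacklevel=2,
        )
    for m in raw_metrics:
        out.append(
            replace(
                m,
                border=m.border_raw / maxima["border"],
                shininess=m.shininess_raw / maxima["shininess"],
                normal=m.normal_raw / maxima["normal"],
            )
        )
    return out


def total_score(metrics: MetricSet, params: FilterParams | None = None,
                squared: bool = True) -> float:
    """Combine normalised metrics: S = S_N / (S_B * S_S^2).

    ``squared=False`` gives the unweighted S = S_N / (S_B * S_S) variant.
    Denominator terms are clamped at ``params.epsilon`` (with a logged
    warning) so a zero metric cannot divide by zero.
    """
    params = params or FilterParams()
    if metrics.border is None or metrics.shininess is None or metrics.normal is None:
        raise DungscoreError("total_score needs batch-normalised metrics")
    sb, ss = metrics.border, metrics.shininess
    if sb < params.epsilon or ss < params.epsilon:
        logger.warning(
            "sample %s: clamping near-zero metric(s) to epsilon=%g in total score",
            metrics.sample_id, params.epsilon,
        )
    sb = max(sb, params.epsilon)
    ss = max(ss, params.epsilon)
    return metrics.normal / (sb * ss**2) if squared else metrics.normal / (sb * ss)


@dataclass(frozen=True)
class Sample:
    """One sample's per-band image stacks, keyed 'VIS' / 'NIR'."""

    sample_id: str
    stacks: Mapping[str, ImageStack]


@dataclass
class BatchResult:
    """Ranked metric sets plus per-sample failure messages."""

    metrics: list[MetricSet]
    errors: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        cols = ["sample_id", "border_raw", "shininess_raw", "normal_raw",
                "border", "shininess", "normal", "total", "rank"]
        return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in self.metrics],
                            columns=cols)


def _stack_for(sample: Sample, metric: str,
               assignment: Mapping[str, str]) -> ImageStack:
    band = assignment.get(metric, "VIS")
    if band in sample.stacks:
        return sample.stacks[band]
    # single-band fallback: use whatever band the sample provides
    (only,) = set(sample.stacks) if len(sample.stacks) == 1 else (band,)
    if only not in sample.stacks:
        raise DungscoreError(f"sample {sample.sample_id}: no stack for band {band}")
    return sample.stacks[only]


def compute_raw_metrics(
    sample: Sample,
    filter_params: FilterParams | None = None,
    seg_params: SegmentationParams | None = None,
    band_assignment: Mapping[str, str] = DEFAULT_BAND_ASSIGNMENT,
) -> tuple[MetricSet, SampleMask]:
    """Segment one sample and compute its three raw metrics.

    The mask comes from the border-metric band's stack and is shared by all
    three metrics (the rig is rigid, so bands are co-registered).
    """
    border_stack = _stack_for(sample, "border", band_assignment)
    shine_stack = _stack_for(sample, "shininess", band_assignment)
    normal_stack = _stack_for(sample, "normal", band_assignment)
    if shine_stack.shape != border_stack.shape or normal_stack.shape != border_stack.shape:
        raise DungscoreError(f"sample {sample.sample_id}: band image sizes differ")
    mask = extract_mask(border_stack, seg_params)
    surface = solve_ps(normal_stack)
    raw = MetricSet(
        sample_id=sample.sample_id,
        border_raw=border_metric(mask),
        shininess_raw=shininess_metric(shine_stack, mask),
        normal_raw=normal_metric(surface, mask, filter_params),
    )
    return raw, mask


def score_batch(
    samples: Sequence[Sample],
    filter_params: FilterParams | None = None,
    seg_params: SegmentationParams | None = None,
    band_assignment: Mapping[str, str] = DEFAULT_BAND_ASSIGNMENT,
    squared: bool = True,
) -> BatchResult:
    """Run the full pipeline over a batch and rank by ascending total score.

    Per-sample failures are isolated: the failing sample is reported in
    ``errors`` and the batch continues.  Rank 1 is the lowest (runniest)
    score; ties are broken by sample_id.
    """
    raws: list[MetricSet] = []
    errors: dict[str, str] = {}
    for sample in samples:
        try:
            raw, _ = compute_raw_metrics(sample, filter_params, seg_params, band_assignment)
            raws.append(raw)
        except DungscoreError as exc:
            errors[sample.sample_id] = f"{type(exc).__name__}: {exc}"
            logger.warning("sample %s failed: %s", sample.sample_id, exc)
    if not raws:
        return BatchResult(metrics=[], errors=errors)
    normed = normalise_batch(raws)
    scored = [replace(m, total=total_score(m, filter_params, squared=squared))
              for m in normed]
    scored.sort(key=lambda m: (m.total, m.sample_id))
    scored = [replace(m, rank=i + 1) for i, m in enumerate(scored)]
    return BatchResult(metrics=scored, errors=errors)
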