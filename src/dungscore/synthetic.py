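"""Parametric synthetic faecal-sample renderer.

Every pipeline stage needs a testable input: a dark, dome-shaped sample on a
lighter flat ground, imaged under four oblique point lights.  This module
builds such scenes from a handful of interpretable parameters and returns,
besides the rendered image stack, the exact ground truth (height field,
outline mask, analytic normals) that the real capture device cannot provide.

Scene model
-----------
* **Outline**: a star-convex blob whose polar radius is
  ``blob_radius * (1 + irregularity * P(theta))``, with P a zero-mean,
  band-limited (harmonics 2-6) periodic perturbation normalised to peak
  amplitude 1, so ``irregularity`` directly bounds the deepest notch.
* **Body**: height rises from a zero collar at the outline through a
  smoothstep of the (Gaussian-smoothed) interior distance field.  Building
  the dome from the distance transform rather than a polar profile keeps
  the rim slope bounded and uniform however ragged the outline is: narrow
  tongues and notches stay low, like real splatter.
* **Roughness**: band-limited noise (Gaussian-filtered white noise,
  correlation length ``roughness_scale``) ramped in from the rim.
* **Shading**: Lambertian plus a narrow Blinn-Phong glint lobe.  The glint
  lobe uses a *micro-facet* normal - the geometric normal jittered by a
  fine-grained (sub-pixel correlation) slope field of RMS ``wet_ripple`` -
  so a wet but geometrically smooth sample still throws abundant,
  light-specific glints while its recovered normal field stays smooth.
  The exponent default (200) is the smallest regime in which no surface
  point glints under more than one rig light, the premise of the
  max-minus-min shininess measure.  Glints in the near infrared are
  strongly attenuated (``NIR_SPECULAR_FACTOR``), reflecting the empirical
  finding that NIR capture suits 3-D analysis while visible light best
  exposes wetness.

The optional ``firmness`` scalar in [0, 1] drives the appearance axes the
way real consistency does - firm samples are rough, matte and compact;
runny samples are smooth, wet-glossy and splattered - via fixed affine maps
(a test harness, not a biological model):

    roughness_amp     = 0.5  + 2.5  * firmness          [height px]
    specular_strength = 0.10 + 0.80 * (1 - firmness)
    irregularity      = 0.05 + 0.30 * (1 - firmness)
    wet_ripple        = 0.02 + 0.18 * (1 - firmness)    [slope RMS]
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .errors import SyntheticSpecError
from .photometric import ImageStack, LightRig

#: rig lights sit this many degrees off the vertical camera axis (compact
#: rig: LEDs close to the lens, as on the physical capture device)
DEFAULT_TILT_DEG = 30.0

#: specular attenuation applied when rendering the NIR band
NIR_SPECULAR_FACTOR = 0.05

#: width (px) of the zero-height collar inside the outline
_RIM_COLLAR = 6.0

#: noise amplitude ramps in over this many px from the rim
_NOISE_RAMP = 8.0

#: the native resolution of the synthetic fixtures relative to the ~4 MP
#: frames the default pixel-unit filter parameters assume
FIXTURE_SCALE = 0.125


def default_rig(band: str = "VIS", tilt_deg: float = DEFAULT_TILT_DEG) -> LightRig:
    """Four-light rig: azimuths 0/90/180/270 at a common tilt from vertical."""
    t = np.deg2rad(tilt_deg)
    az = np.deg2rad([0.0, 90.0, 180.0, 270.0])
    vecs = np.stack([np.sin(t) * np.cos(az), np.sin(t) * np.sin(az),
                     np.full(4, np.cos(t))], axis=1)
    return LightRig(directions=vecs / np.linalg.norm(vecs, axis=1, keepdims=True),
                    band=band)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return 3.0 * x**2 - 2.0 * x**3


@dataclass(frozen=True)
class SyntheticSpec:
    """Scene parameters; identical spec + seed gives bit-identical output."""

    image_size: int = 256
    blob_radius: float = 80.0  # px
    irregularity: float = 0.15  # peak radial outline perturbation, fraction
    roughness_amp: float = 1.5  # height-noise amplitude, px
    roughness_scale: float = 5.0  # noise correlation length, px
    specular_strength: float = 0.3
    specular_exponent: float = 200.0
    wet_ripple: float = 0.1  # micro-facet slope RMS (specular only)
    wet_ripple_scale: float = 0.8  # micro-facet correlation length, px
    sample_albedo: float = 0.35
    background_albedo: float = 0.75
    dome_height: float = 12.0  # px
    firmness: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sample_albedo < 1 or not 0 < self.background_albedo < 1:
            raise SyntheticSpecError("albedos must lie in (0, 1)")
        if self.background_albedo <= self.sample_albedo:
            raise SyntheticSpecError("background must be lighter than the sample")
        if min(self.irregularity, self.roughness_amp, self.specular_strength,
               self.wet_ripple) < 0:
            raise SyntheticSpecError("amplitudes must be >= 0")
        if min(self.specular_exponent, self.roughness_scale,
               self.wet_ripple_scale, self.blob_radius) <= 0:
            raise SyntheticSpecError("exponents, scales and radii must be > 0")
        if self.firmness is not None and not 0 <= self.firmness <= 1:
            raise SyntheticSpecError("firmness must lie in [0, 1]")

    def resolved(self) -> "SyntheticSpec":
        """Apply the firmness -> appearance affine maps, if firmness is set."""
        if self.firmness is None:
            return self
        f = self.firmness
        return replace(
            self,
            firmness=None,
            roughness_amp=0.5 + 2.5 * f,
            specular_strength=0.10 + 0.80 * (1 - f),
            irregularity=0.05 + 0.30 * (1 - f),
            wet_ripple=0.02 + 0.18 * (1 - f),
        )


@dataclass
class SyntheticSurface:
    """Ground truth for one rendered scene."""

    height: np.ndarray  # (H, W), px, 0 outside the blob
    mask: np.ndarray  # (H, W) bool, blob interior
    normals: np.ndarray  # (H, W, 3) unit, from height gradients


def _outline_radius(spec: SyntheticSpec, theta: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Band-limited, zero-mean, peak-1 outline perturbation."""
    ks = np.arange(2, 7)
    amps = rng.standard_normal(len(ks)) / ks
    phases = rng.uniform(0, 2 * np.pi, len(ks))
    p = np.zeros_like(theta)
    for k, a, ph in zip(ks, amps, phases):
        p += a * np.cos(k * theta + ph)
    peak = np.abs(p).max()
    if peak > 0:
        p /= peak
    radius = spec.blob_radius * (1 + spec.irregularity * p)
    if radius.min() <= 0:
        raise SyntheticSpecError(
            f"irregularity {spec.irregularity} drives the outline radius non-positive"
        )
    return radius


def generate_surface(spec: SyntheticSpec) -> SyntheticSurface:
    """Build the height field, truth mask and analytic normals for a spec."""
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = yy - c, xx - c
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    radius = _outline_radius(spec, theta, rng)
    mask = r <= radius
    if not mask.any():
        raise SyntheticSpecError("blob lies outside the image")
    d = distance_transform_edt(mask)
    # dome through a smoothed interior-distance level set: height -> 0 at the
    # rim everywhere (no cliffs at concave notches), narrow tongues stay low
    g = gaussian_filter(d, _RIM_COLLAR)
    height = spec.dome_height * _smoothstep(
        np.clip((g - _RIM_COLLAR) / (0.35 * spec.blob_radius), 0.0, 1.0)
    )
    if spec.roughness_amp > 0:
        noise = gaussian_filter(rng.standard_normal((n, n)), spec.roughness_scale,
                                mode="wrap")
        noise /= noise.std()
        ramp = _smoothstep(np.minimum(d / _NOISE_RAMP, 1.0))
        height = height + spec.roughness_amp * noise * ramp
    height = np.where(mask, height, 0.0)
    gy, gx = np.gradient(height)  # gy = dh/drow, gx = dh/dcol
    normals = np.stack([-gx, -gy, np.ones_like(height)], axis=-1)
    normals /= np.linalg.norm(normals, axis=-1, keepdims=True)
    return SyntheticSurface(height=height, mask=mask, normals=normals)


def _micro_normals(surface: SyntheticSurface, spec: SyntheticSpec) -> np.ndarray:
    """Geometric normals jittered by the wet-film micro-slope field."""
    if spec.wet_ripple == 0:
        return surface.normals
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EC]))
    n = spec.image_size
    jx = gaussian_filter(rng.standard_normal((n, n)), spec.wet_ripple_scale)
    jy = gaussian_filter(rng.standard_normal((n, n)), spec.wet_ripple_scale)
    jx /= jx.std()
    jy /= jy.std()
    micro = surface.normals + spec.wet_ripple * np.stack(
        [jx, jy, np.zeros_like(jx)], axis=-1
    )
    return micro / np.linalg.norm(micro, axis=-1, keepdims=True)


def render_stack(surface: SyntheticSurface, spec: SyntheticSpec, rig: LightRig,
                 quantise: bool = False) -> ImageStack:
    """Shade the surface under each rig light: Lambert + micro-facet glints.

    The background is a matte Lambertian plane of ``background_albedo`` with
    normal (0, 0, 1); glints apply only inside the sample and are attenuated
    by ``NIR_SPECULAR_FACTOR`` when the rig's band is NIR.  ``quantise``
    rounds the images to 8-bit levels, emulating real capture.
    """
    spec = spec.resolved()
    albedo = np.where(surface.mask, spec.sample_albedo, spec.background_albedo)
    strength = spec.specular_strength
    if rig.band == "NIR":
        strength *= NIR_SPECULAR_FACTOR
    micro = _micro_normals(surface, spec) if strength > 0 else surface.normals
    view = np.array([0.0, 0.0, 1.0])
    images = []
    for light in rig.directions:
        img = albedo * np.clip(surface.normals @ light, 0.0, None)
        if strength > 0:
            half = light + view
            half = half / np.linalg.norm(half)
            ndoth = np.clip(micro @ half, 0.0, None)
            img = img + np.where(surface.mask,
                                 strength * ndoth**spec.specular_exponent, 0.0)
        images.append(np.clip(img, 0.0, 1.0))
    arr = np.stack(images)
    if quantise:
        arr = np.round(arr * 255) / 255
    return ImageStack(images=arr, rig=rig)


@dataclass
class CohortSample:
    """One synthetic cohort member: parameters, truth, and per-band stacks."""

    spec: SyntheticSpec
    surface: SyntheticSurface
    stacks: dict[str, ImageStack] = field(default_factory=dict)


def generate_cohort(
    n: int,
    firmness_range: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
    base_spec: SyntheticSpec | None = None,
    bands: tuple[str, ...] = ("VIS", "NIR"),
    quantise: bool = False,
) -> list[CohortSample]:
    """Render n samples with firmness evenly spaced over the range.

    Each member gets an independent sub-seed derived from ``seed``; the same
    (n, range, seed) always reproduces the same cohort.  Members are ordered
    by firmness; each requested band is rendered with its own default rig
    over the same surface (the rig is rigid, so bands are co-registered).
    """
    if n < 2:
        raise SyntheticSpecError("a cohort needs n >= 2")
    base = base_spec or SyntheticSpec()
    firmness = np.linspace(firmness_range[0], firmness_range[1], n)
    sub_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    cohort = []
    for f, s in zip(firmness, sub_seeds):
        member_spec = replace(base, firmness=float(f), seed=int(s))
        surface = generate_surface(member_spec)
        stacks = {b: render_stack(surface, member_spec, default_rig(band=b),
                                  quantise=quantise) for b in bands}
        cohort.append(CohortSample(spec=member_spec, surface=surface, stacks=stacks))
    return cohort


def iter_cohort_samples(cohort: list[CohortSample],
                        prefix: str = "synthetic") -> Iterator:
    """Adapt a cohort to the scoring batch interface (metrics.Sample)."""
    from .metrics import Sample

    width = len(str(len(cohort)))
    for i, member in enumerate(cohort):
        yield Sample(sample_id=f"{prefix}-{i:0{width}d}", stacks=member.stacks)
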