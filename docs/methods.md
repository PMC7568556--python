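# Methods

This note records the models, parameter choices and numerical conventions
behind `dungscore`, and what the synthetic tests do and do not establish.

## Coordinate and capture conventions

Image row 0 is at the top; x increases along columns (rightward), y along
rows (downward), z points toward the camera. Light direction vectors point
from the surface toward the light and are unit length; the camera is
orthographic, looking along −z. For a height field h(x, y) measured toward
the camera the outward unit normal is proportional to
(−∂h/∂x, −∂h/∂y, 1). Colour inputs are reduced to grayscale with luma
weights before any processing; 8- and 16-bit integers are rescaled to
[0, 1] by the dtype maximum.

## Photometric stereo

The solver is classical Lambertian least squares: for n ≥ 3 lights,
`g = pinv(L) I` per pixel, with albedo = |g| and N = g/|g|. Choices:

* **Shadowed measurements** (intensities clamped at zero by the renderer
  or the scene) stay in the system. With four lights this biases normals
  only where a light is occluded; the alternative — per-pixel light
  subset selection — is not needed at the accuracy the metrics require
  and would cost determinism in degenerate cases.
* **Degenerate pixels**: albedo below 1e-6 of the frame maximum, or a
  back-facing least-squares solution, yields the canonical normal
  (0, 0, 1) (and albedo 0 in the first case). This keeps NaNs out of the
  downstream filtering.
* **Rig validation**: at least three lights, unit norms to 1e-6, and rank
  3 of the direction matrix; violations raise before any solve.

Depth integration uses the Frankot–Chellappa projection: the gradient
field p = −n_x/n_z, q = −n_y/n_z is projected onto integrable fields in
the DFT basis. The DFT cannot represent a nonzero mean gradient, so the
affine component is integrated separately and added back — a constant
slope (tilted plane) is therefore recovered exactly. n_z is clamped at
1e-3 (with a warning) to keep gradients finite; output depth is
mean-centred, since depth is only defined up to a constant. Scoring never
uses depth; integration artefacts (wrap-around leakage from the frame
boundary) are confined to visual inspection use.

## Segmentation

Pipeline: I_min → Otsu threshold → foreground = (I_min ≤ t) → fill holes
→ erode (disc, radius 5 px at ~4 MP) → keep largest 4-connected component
→ fill holes again. The final fill guarantees the hole-free invariant;
4-connectivity is used everywhere for determinism. The Otsu
implementation histograms into 256 bins over [0, 1], scores every split
by between-class variance computed from exact per-bin intensity sums (not
bin centres), breaks ties toward the lowest threshold, and returns the
upper edge of the last foreground bin so that `image <= threshold`
reproduces the optimal partition exactly. A foreground fraction outside
(0.01, 0.9) warns that the dark-sample-on-light-ground premise may be
violated; an empty post-clean-up foreground is an error.

## Metrics

* **Border**: 1 − mask area / convex-hull area. Hull rasterisation
  follows scikit-image's convention; other rasterisers differ by a
  boundary-pixel fringe (≲ 2% on a 64 px shape, vanishing with size).
* **Shininess**: mean of I_max − I_min over the mask. Bounded in [0, 1];
  zero iff every light sees the same intensity at every mask pixel.
* **Normal**: on the n_z field, N′ = |GF_σ(n_z) − n_z| with σ = 5 px;
  then a weighted median (centre pixel + its 20 nearest neighbours by
  Euclidean distance, centre counted three times — an odd 23-element
  multiset, so the median is an exact order statistic); then the sample
  standard deviation (n−1) over a radius-51 px disc, computed via FFT
  convolution of the padded field. All filters use reflect padding and
  run on the full frame; the mask applies only at the final mean. The
  high-pass isolates fine 3-D texture, the median suppresses
  highlight-induced speckle in the recovered normals, and the local
  standard deviation turns residual texture into a roughness map.
* **Resolution scaling**: σ and the SDF radius are pixel-unit parameters
  tied to ~4 MP capture; `FilterParams.scale` multiplies both (the 256 px
  synthetic fixtures use scale = 0.125 → σ = 0.625, radius 6, erosion
  radius 1). The median neighbourhood is deliberately *not* scaled: it is
  a small denoising primitive whose job — rejecting pixel-scale specular
  speckle — does not shrink with frame size.
* **Normalisation** divides each metric by its maximum over the batch
  being scored, so each metric attains 1 for some sample. Consequence:
  scores are comparable within a batch, not across batches — raw values
  are always retained for cross-batch work, and single-sample batches
  warn (total ≡ 1 by construction).
* **Total**: S = S_N / (S_B · S_S²), with denominator terms clamped at
  ε = 1e-6 (logged). The squared shininess weighting separates samples
  better than the unweighted ratio, which remains available
  (`squared=False`). Batch ranking is ascending in S with ties broken by
  sample id; per-sample failures are isolated and reported while the
  batch continues.
* **Band assignment**: by default the normal metric is computed from the
  NIR stack and border/shininess from the VIS stack (single-band input
  falls back to whatever is present, with a warning). NIR carries much
  weaker specular gloss, which is precisely why it suits the 3-D
  roughness measurement, while visible light best exposes wetness.

## Synthetic scenes

The generator's job is to emulate the capture situation — a dark,
irregular, possibly glossy dome on a lighter matte ground under four
known lights — with exact ground truth. Construction:

* **Outline**: polar radius `R(θ) = R₀(1 + a·P(θ))`, P a random
  band-limited harmonic series (orders 2–6) normalised to peak amplitude
  1, so the irregularity parameter a directly bounds the deepest notch.
  Default R₀ = 80 px in a 256 px frame.
* **Body**: height rises from a zero collar at the outline through a
  smoothstep of the Gaussian-smoothed interior distance transform
  (collar 6 px, rise length 0.35·R₀, peak 12 px). Building the dome from
  the distance field — rather than any polar profile — keeps the rim
  slope bounded and uniform for arbitrarily ragged outlines: narrow
  tongues and concave notches stay low, as physical splatter does.
  Earlier polar constructions produced cliffs at concave notches whose
  high-frequency content swamped the roughness metric for exactly the
  runny (irregular) samples, inverting the metric's meaning.
* **Roughness**: Gaussian-filtered white noise (correlation length 5 px,
  unit variance) scaled by the roughness amplitude and ramped in over
  8 px from the rim.
* **Shading**: Lambertian, plus a Blinn–Phong glint lobe applied only
  inside the sample and only to a *micro-facet* normal — the geometric
  normal jittered by a sub-pixel-correlation slope field of RMS
  `wet_ripple`. This separates two physical scales: a runny sample is
  geometrically smooth (its recovered normal field should be quiet) yet
  its wet film glints abundantly because micro-slopes reach the mirror
  condition. Exponent 200 is the regime in which no surface point glints
  under more than one of the rig's lights — the premise of the
  max-minus-min shininess measure (verified by construction: at the
  default 30° light tilt the half-vectors are ~21° apart, twice the
  lobe's acceptance angle). NIR renders attenuate the glint strength by
  ×0.05, the renderer's expression of NIR's suitability for 3-D work.
  Lights sit 30° off vertical: close enough to the camera axis that
  gently rippled wet surfaces present glints, oblique enough for
  well-conditioned photometric stereo.
* **Firmness maps** (fixed affine, a test harness rather than a
  biological model): roughness 0.5 + 2.5·f px, specular strength
  0.10 + 0.80·(1−f), irregularity 0.05 + 0.30·(1−f), wet ripple
  0.02 + 0.18·(1−f). Cohorts space firmness evenly and derive
  independent member seeds from one root seed; identical inputs are
  bit-reproducible.

What the synthetic cohort does establish: metric directionality (each
metric tracks its generating parameter), rank recovery of a firmness
gradient, the qualitative correlation structure (roughness opposes
shininess and border; shininess and border move together), and
segmentation overlap ≥ 0.95 against truth masks. What it does not: any
claim about real faecal appearance — wet organic matter has spatially
varying albedo, subsurface scattering and fibres/particles the renderer
omits — nor agreement with any particular physical rig's absolute metric
values, which depend on optics, exposure and resolution. Rank recovery is
not perfect by construction: over ten root seeds, nine give Spearman
ρ ≥ 0.9 and one gives 0.84 via adjacent swaps at the runny end, where the
metrics genuinely trade off.

## Content detection

Corn kernels and fibre fragments are detected on a single image combined
from the stack(s): per-pixel mean, median (lower-middle order statistic
for even counts) or minimum. Maximum-combination is refused by design —
it amplifies exactly the specular highlights that confound detection,
whereas the minimum cancels anything that appears under a single light.
The image is tiled into non-overlapping square patches (default 224 px;
right/bottom remainders dropped) labelled {neither, fibre, corn}. The
classifier interface is pluggable (`fit` / `predict_proba` on patches); a
deep transfer-learned network is the natural production choice but is
deliberately out of scope — the shipped baseline (16-bin intensity
histogram, 8-orientation gradient-energy descriptors and summary
statistics, multinomial logistic regression) exists so the combination
and tiling pipeline is testable at desk scale, reaching ~0.94 held-out
accuracy on the separable synthetic corpus. A training corpus of one
class yields a constant predictor rather than an error.

## Known limitations

* Segmentation presumes the ground is lighter than the sample; on dark
  ground the orientation warning fires and the mask is unreliable.
* Normalisation is batch-relative; totals from different batches are not
  directly comparable (use raw metrics).
* The weighted-median neighbourhood and centre weighting are one
  reasonable reading of a centre-weighted 20-neighbourhood; other
  readings shift the normal metric by a smooth monotone factor.
* Depth integration assumes periodic boundary conditions; use it for
  inspection, not measurement, near the frame border.
* The total score is a relative ordering device; mapping it onto the
  established 1–5 manure score requires calibration data and is out of
  scope.
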