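"""Image combination, patch tiling and patch classification for content detection.

Undigested corn kernels and long fibres are detected on a single combined
image built from the multi-illumination stack(s).  Combination by per-pixel
*minimum* suppresses specular highlights (each highlight appears under only
one light) and works best; *median* is a good alternative; per-pixel
*maximum* is deliberately unsupported because it amplifies specularities and
confounds classification.

The combined image is tiled into non-overlapping square patches, each
labelled one of {neither, fibre, corn}.  Classification is pluggable: any
object with ``fit(patches, labels)`` / ``predict_proba(patches)`` works, and
a deterministic classical baseline (intensity histogram + oriented-gradient
energy features, multinomial logistic regression) ships with the package so
the pipeline is testable without a GPU or a large labelled corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, rotate, sobel
from sklearn.linear_model import LogisticRegression

from .errors import ClassifierError, ImageFormatError, UnsupportedMethodError
from .photometric import ImageStack

CLASSES = ("neither", "fibre", "corn")
COMBINE_METHODS = ("mean", "median", "min", "individual")


@dataclass(frozen=True)
class CombinedImage:
    image: np.ndarray
    method: str
    bands_used: tuple[str, ...]


@dataclass
class PatchSet:
    """Non-overlapping square patches in row-major order, with optional labels."""

    patches: list[tuple[int, int, np.ndarray]]  # (row, col, patch)
    grid: int
    labels: list[str] | None = None

    def arrays(self) -> list[np.ndarray]:
        return [p for _, _, p in self.patches]


def combine(stacks: Sequence[ImageStack] | ImageStack, method: str,
            index: int | None = None) -> CombinedImage:
    """Element-wise mean / median / min across all images of the given stacks.

    ``individual`` selects image ``index`` of the (single) stack.  The median
    of an even image count is the lower-middle order statistic.  ``max`` is
    rejected: it emphasises specular highlights and defeats the detector.
    """
    if isinstance(stacks, ImageStack):
        stacks = [stacks]
    if method == "max":
        raise UnsupportedMethodError(
            "max-combination is unsupported: it emphasises specularities"
        )
    if method not in COMBINE_METHODS:
        raise UnsupportedMethodError(f"method must be one of {COMBINE_METHODS}")
    shapes = {s.shape for s in stacks}
    if len(shapes) != 1:
        raise ImageFormatError(f"stacks have mismatched image sizes: {sorted(shapes)}")
    bands = tuple(dict.fromkeys(s.rig.band for s in stacks))
    imgs = np.concatenate([s.images for s in stacks], axis=0)
    if method == "individual":
        if index is None:
            raise UnsupportedMethodError("method 'individual' requires an index")
        out = imgs[index]
    elif method == "mean":
        out = imgs.mean(axis=0)
    elif method == "min":
        out = imgs.min(axis=0)
    else:  # median, lower-middle for even counts
        out = np.sort(imgs, axis=0)[(imgs.shape[0] - 1) // 2]
    return CombinedImage(image=out, method=method, bands_used=bands)


def tile(image: CombinedImage | np.ndarray, patch_px: int = 224) -> PatchSet:
    """Cut a non-overlapping patch grid; right/bottom remainders are dropped."""
    arr = image.image if isinstance(image, CombinedImage) else np.asarray(image)
    if patch_px < 16:
        raise ValueError("patch_px must be >= 16")
    h, w = arr.shape
    if patch_px > h or patch_px > w:
        raise ImageFormatError(f"patch {patch_px} px exceeds image {arr.shape}")
    patches = [
        (r, c, arr[r : r + patch_px, c : c + patch_px])
        for r in range(0, h - patch_px + 1, patch_px)
        for c in range(0, w - patch_px + 1, patch_px)
    ]
    return PatchSet(patches=patches, grid=patch_px)


class PatchClassifier(Protocol):
    """fit/predict contract: patches are 2-D float arrays in [0, 1]."""

    def fit(self, patches: Sequence[np.ndarray], labels: Sequence[str]) -> "PatchClassifier": ...

    def predict_proba(self, patches: Sequence[np.ndarray]) -> np.ndarray: ...


def _patch_features(patch: np.ndarray, hist_bins: int = 16,
                    n_orient: int = 8) -> np.ndarray:
    """Intensity histogram + oriented gradient energy descriptors."""
    hist, _ = np.histogram(patch, bins=hist_bins, range=(0.0, 1.0))
    hist = hist / patch.size
    gy = sobel(patch, axis=0, mode="reflect")
    gx = sobel(patch, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    orient = np.mod(np.arctan2(gy, gx), np.pi)  # orientation, not direction
    edges = np.linspace(0, np.pi, n_orient + 1)
    which = np.clip(np.digitize(orient.ravel(), edges) - 1, 0, n_orient - 1)
    energy = np.bincount(which, weights=mag.ravel() ** 2, minlength=n_orient)
    total = energy.sum()
    energy = energy / total if total > 0 else energy
    sorted_e = np.sort(energy)[::-1]
    aniso = sorted_e[0] - sorted_e[1]  # ridge-like patches concentrate energy
    return np.concatenate([hist, energy, [mag.mean(), mag.std(), aniso,
                                          patch.mean(), patch.std(), patch.max()]])


@dataclass
class BaselineClassifier:
    """Hand-crafted features + multinomial logistic regression."""

    C: float = 1.0
    max_iter: int = 1000
    _model: LogisticRegression | None = field(default=None, repr=False)
    _single_class: str | None = field(default=None, repr=False)

    def fit(self, patches: Sequence[np.ndarray], labels: Sequence[str]) -> "BaselineClassifier":
        if len(patches) != len(labels):
            raise ClassifierError("patch and label counts differ")
        classes = sorted(set(labels))
        if len(classes) == 1:  # degenerate corpus: constant predictor
            self._single_class = classes[0]
            self._model = None
            return self
        self._single_class = None
        X = np.stack([_patch_features(p) for p in patches])
        self._model = LogisticRegression(C=self.C, max_iter=self.max_iter)
        self._model.fit(X, np.asarray(labels))
        return self

    def predict_proba(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        if self._model is None and self._single_class is None:
            raise ClassifierError("classifier used before fitting")
        if self._single_class is not None:
            return np.ones((len(patches), 1))
        X = np.stack([_patch_features(p) for p in patches])
        return self._model.predict_proba(X)

    @property
    def classes_(self) -> np.ndarray:
        if self._single_class is not None:
            return np.array([self._single_class])
        if self._model is None:
            raise ClassifierError("classifier used before fitting")
        return self._model.classes_


def classify_patches(patchset: PatchSet,
                     classifier: PatchClassifier) -> tuple[list[str], np.ndarray]:
    """Label every patch; per-patch class scores sum to 1."""
    proba = classifier.predict_proba(patchset.arrays())
    proba = proba / proba.sum(axis=1, keepdims=True)
    classes = getattr(classifier, "classes_", np.array(CLASSES))
    labels = [str(classes[i]) for i in np.argmax(proba, axis=1)]
    return labels, proba


# ---------------------------------------------------------------------------
# synthetic patch corpus (test harness; labelled in filename and here as such)
# ---------------------------------------------------------------------------

def _base_texture(rng: np.random.Generator, size: int) -> np.ndarray:
    tex = gaussian_filter(rng.standard_normal((size, size)), 2.0)
    tex = 0.35 + 0.08 * tex / tex.std()
    return tex


def _add_corn(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.uniform(0.2 * size, 0.8 * size, 2)
        a, b = rng.uniform(0.06 * size, 0.12 * size, 2)
        ang = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
        v = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
        blob = np.exp(-((u / a) ** 2 + (v / b) ** 2))
        img = img + rng.uniform(0.4, 0.6) * blob
    return img


def _add_fibre(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    size = img.shape[0]
    for _ in range(rng.integers(1, 3)):
        ridge = np.zeros((size, size))
        row = int(rng.uniform(0.3 * size, 0.7 * size))
        width = max(1, int(0.02 * size))
        ridge[row - width : row + width + 1, :] = 1.0
        ridge = gaussian_filter(ridge, 1.0)
        ridge = rotate(ridge, rng.uniform(0, 180), reshape=False, order=1)
        img = img + rng.uniform(0.3, 0.5) * ridge / max(ridge.max(), 1e-9)
    return img


def make_synthetic_patches(
    n_per_class: int,
    patch_px: int = 48,
    seed: int = 0,
    specular_contamination: float = 0.0,
    n_lights: int = 4,
) -> tuple[list[list[np.ndarray]], list[str]]:
    """Generate labelled synthetic patch *stacks* (one image per light).

    corn = bright ellipse blobs, fibre = elongated bright ridges, neither =
    plain smooth texture.  The true content appears identically under every
    light; with ``specular_contamination > 0``, each light's image may also
    carry that many (in expectation) bright specular spots unique to that
    light, which min-combination removes and mean-combination only dilutes.

    Returns (stacks, labels): stacks[i] is a list of ``n_lights`` images.
    """
    rng = np.random.default_rng(seed)
    stacks: list[list[np.ndarray]] = []
    labels: list[str] = []
    yy, xx = np.mgrid[0:patch_px, 0:patch_px].astype(float)
    for cls in CLASSES:
        for _ in range(n_per_class):
            base = _base_texture(rng, patch_px)
            if cls == "corn":
                base = _add_corn(base, rng)
            elif cls == "fibre":
                base = _add_fibre(base, rng)
            per_light = []
            for _ in range(n_lights):
                img = base + 0.02 * rng.standard_normal(base.shape)
                n_spots = rng.poisson(specular_contamination)
                for _ in range(n_spots):
                    cy, cx = rng.uniform(0, patch_px, 2)
                    sig = rng.uniform(0.04, 0.08) * patch_px
                    img = img + 0.9 * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)
                                               / (2 * sig**2)))
                per_light.append(np.clip(img, 0.0, 1.0))
            stacks.append(per_light)
            labels.append(cls)
    return stacks, labels
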