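"""Photometric stereo: Lambertian inversion and normal-field integration.

A fixed camera looks straight down (+z toward the camera) at a sample lit in
turn by n >= 3 point lights with known unit direction vectors (surface ->
light).  Under the Lambertian model each pixel's intensity in image i is

    I_i = albedo * max(0, N . L_i)

so stacking the n equations gives, per pixel, a linear system whose
least-squares solution g satisfies albedo = |g| and N = g / |g|.

Coordinate convention (used by every module in this package): image row 0 at
the top, x increases rightward along columns, y increases downward along
rows, z points toward the camera.  For a height field h(x, y) measured toward
the camera the outward normal is proportional to (-dh/dx, -dh/dy, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import IllPosedError, RigConfigError

BANDS = ("VIS", "NIR")

#: pixels whose recovered albedo falls below this fraction of the image
#: maximum are treated as signal-free and assigned the canonical normal
ALBEDO_FLOOR_FRAC = 1e-6

#: n_z values at or below this are clamped before computing depth gradients
NZ_FLOOR = 1e-3


@dataclass(frozen=True)
class LightRig:
    """Ordered unit light-direction vectors (surface -> light) plus band tag."""

    directions: np.ndarray  # (n, 3), unit rows
    band: str = "VIS"

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise RigConfigError(f"directions must be (n, 3), got {d.shape}")
        if d.shape[0] < 3:
            raise RigConfigError(f"need >= 3 lights, got {d.shape[0]}")
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise RigConfigError("light directions must be unit vectors (|norm - 1| <= 1e-6)")
        if np.linalg.matrix_rank(d) < 3:
            raise IllPosedError("light-direction matrix has rank < 3; PS is ill-posed")
        if self.band not in BANDS:
            raise RigConfigError(f"band must be one of {BANDS}, got {self.band!r}")
        object.__setattr__(self, "directions", d)

    @classmethod
    def from_vectors(cls, vectors: Sequence[Sequence[float]], band: str = "VIS") -> "LightRig":
        """Build a rig from arbitrary-length vectors, normalising each to unit length."""
        v = np.asarray(vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise RigConfigError(f"expected a list of 3-vectors, got shape {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise RigConfigError("zero-length light vector")
        return cls(v / norms[:, None], band)

    def __len__(self) -> int:
        return len(self.directions)


@dataclass(frozen=True)
class ImageStack:
    """Co-registered intensity images aligned one-to-one with the rig's lights."""

    images: np.ndarray  # (n, H, W) float in [0, 1]
    rig: LightRig

    def __post_init__(self) -> None:
        imgs = np.asarray(self.images, dtype=float)
        if imgs.ndim != 3:
            raise RigConfigError(f"images must be (n, H, W), got {imgs.shape}")
        if imgs.shape[0] != len(self.rig):
            raise RigConfigError(
                f"{imgs.shape[0]} images but rig has {len(self.rig)} lights"
            )
        if imgs.min() < -1e-9 or imgs.max() > 1 + 1e-9:
            raise RigConfigError("intensities must lie in [0, 1]")
        object.__setattr__(self, "images", np.clip(imgs, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class SurfaceMap:
    """Per-pixel albedo and unit, camera-facing surface normals; optional depth."""

    albedo: np.ndarray  # (H, W) >= 0
    normals: np.ndarray  # (H, W, 3), unit, n_z >= 0
    depth: np.ndarray | None = field(default=None)

    @property
    def nz(self) -> np.ndarray:
        return self.normals[..., 2]


def solve_ps(stack: ImageStack) -> SurfaceMap:
    """Recover albedo and unit normals by per-pixel Lambertian least squares.

    Shadowed (clamped-to-zero) measurements are kept in the system; pixels
    whose solution norm falls below ``ALBEDO_FLOOR_FRAC`` of the image
    maximum are assigned albedo 0 and the canonical normal (0, 0, 1), as are
    the rare pixels whose least-squares normal points away from the camera.
    """
    L = stack.rig.directions  # (n, 3)
    n, h, w = stack.images.shape
    I = stack.images.reshape(n, -1)  # noqa: E741
    g = np.linalg.pinv(L) @ I  # (3, P)
    albedo = np.linalg.norm(g, axis=0)
    floor = ALBEDO_FLOOR_FRAC * albedo.max() if albedo.max() > 0 else 0.0
    good = albedo > floor
    normals = np.zeros((3, albedo.size))
    normals[2] = 1.0
    normals[:, good] = g[:, good] / albedo[good]
    albedo = np.where(good, albedo, 0.0)
    # unphysical back-facing solutions get the canonical normal
    back = normals[2] < 0
    normals[:, back] = np.array([0.0, 0.0, 1.0])[:, None]
    return SurfaceMap(
        albedo=albedo.reshape(h, w),
        normals=np.moveaxis(normals.reshape(3, h, w), 0, -1),
    )


def integrate_depth(normals: np.ndarray, nz_floor: float = NZ_FLOOR) -> np.ndarray:
    """Integrate a unit normal field to a mean-centred depth map.

    Solves min_z || dz/dx - p ||^2 + || dz/dy - q ||^2 with p = -n_x/n_z and
    q = -n_y/n_z, using the Frankot–Chellappa frequency-domain projection
    onto integrable fields.  The mean (affine) gradient component, which the
    periodic DFT basis cannot represent, is integrated separately and added
    back, so constant-slope fields (tilted planes) are recovered exactly.
    Depth is defined up to an additive constant; the output is mean-centred.
    """
    normals = np.asarray(normals, dtype=float)
    if normals.ndim != 3 or normals.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) normal field, got {normals.shape}")
    nz = normals[..., 2]
    if np.any(nz <= nz_floor):
        warnings.warn(
            f"{int(np.sum(nz <= nz_floor))} pixels have n_z <= {nz_floor}; "
            "clamping before integration",
            stacklevel=2,
        )
        nz = np.maximum(nz, nz_floor)
    p = -normals[..., 0] / nz  # dz/dx, x = column index
    q = -normals[..., 1] / nz  # dz/dy, y = row index
    h, w = p.shape
    p0, q0 = p - p.mean(), q - q.mean()
    wx = 2.0 * np.pi * np.fft.fftfreq(w)[None, :]
    wy = 2.0 * np.pi * np.fft.fftfreq(h)[:, None]
    denom = wx**2 + wy**2
    denom[0, 0] = 1.0  # DC handled below
    z_hat = (-1j * wx * np.fft.fft2(p0) - 1j * wy * np.fft.fft2(q0)) / denom
    z_hat[0, 0] = 0.0
    z = np.real(np.fft.ifft2(z_hat))
    yy, xx = np.mgrid[0:h, 0:w]
    z = z + p.mean() * xx + q.mean() * yy
    return z - z.mean()
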