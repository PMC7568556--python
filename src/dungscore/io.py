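"""Loading image stacks and light-rig configurations from disk.

Rig configs are YAML (or JSON, a YAML subset) files::

    band: VIS
    lights:
      - [0.5, 0.0, 0.866]
      - [0.0, 0.5, 0.866]
      - [-0.5, 0.0, 0.866]
      - [0.0, -0.5, 0.866]

Vectors point from the surface toward each light and are normalised on load.
Images are 8- or 16-bit PNG/TIFF, single- or 3-channel; colour is reduced to
grayscale with luma weights and integer intensities are rescaled to [0, 1]
by the dtype maximum.
"""

from __future__ import annotations

import os
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.color import rgb2gray

from .errors import ImageFormatError, RigConfigError
from .photometric import ImageStack, LightRig


def load_rig(path: str | os.PathLike) -> LightRig:
    """Read a YAML/JSON rig config, normalise vectors, validate rank and band."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "lights" not in cfg:
        raise RigConfigError(f"{path}: rig config must be a mapping with a 'lights' key")
    return LightRig.from_vectors(cfg["lights"], band=str(cfg.get("band", "VIS")).upper())


def save_rig(rig: LightRig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"band": rig.band, "lights": [list(map(float, v)) for v in rig.directions]},
            fh,
        )


def read_intensity_image(path: str | os.PathLike) -> np.ndarray:
    """Read one image as a float (H, W) intensity array in [0, 1]."""
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable file
        raise ImageFormatError(f"cannot decode image {path}: {exc}") from exc
    if raw.ndim == 3:
        if raw.shape[2] == 4:
            raw = raw[..., :3]
        raw = rgb2gray(raw)  # rgb2gray also rescales integer dtypes to [0, 1]
        return np.clip(raw.astype(float), 0.0, 1.0)
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(float) / np.iinfo(raw.dtype).max
    return np.clip(raw.astype(float), 0.0, 1.0)


def write_intensity_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] float array as an 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def load_stack(paths: Sequence[str | os.PathLike], rig_config: str | os.PathLike) -> ImageStack:
    """Load ordered per-light images plus their rig into an :class:`ImageStack`.

    Image order must match the order of the rig's light directions.
    """
    rig = load_rig(rig_config)
    if len(paths) != len(rig):
        raise RigConfigError(
            f"{len(paths)} images supplied but rig {rig_config} has {len(rig)} lights"
        )
    images = [read_intensity_image(p) for p in paths]
    shapes = {img.shape for img in images}
    if len(shapes) != 1:
        raise ImageFormatError(f"images have mismatched sizes: {sorted(shapes)}")
    return ImageStack(images=np.stack(images), rig=rig)
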