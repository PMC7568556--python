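"""Shared fixtures: fixture-resolution parameters and synthetic scenes.

The synthetic fixtures are 256 px frames, one eighth of the ~4 MP capture
resolution the default pixel-unit filter parameters assume, so filter and
morphology sizes are run at scale = 0.125.
"""

import numpy as np
import pytest

from dungscore import (
    FilterParams,
    ImageStack,
    SegmentationParams,
    SyntheticSpec,
    default_rig,
    generate_cohort,
    generate_surface,
    render_stack,
)
from dungscore.synthetic import FIXTURE_SCALE

#: root seed used by the demo cohort throughout tests, examples and README
DEMO_SEED = 7


@pytest.fixture(scope="session")
def filter_params() -> FilterParams:
    return FilterParams(scale=FIXTURE_SCALE)


@pytest.fixture(scope="session")
def seg_params() -> SegmentationParams:
    return SegmentationParams(scale=FIXTURE_SCALE)


@pytest.fixture(scope="session")
def rig():
    return default_rig("VIS")


@pytest.fixture(scope="session")
def hemisphere():
    """Analytic hemisphere: mask, unit normals and height, radius 70 px."""
    n, radius = 192, 70.0
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = yy - c, xx - c
    r2 = dy**2 + dx**2
    mask = r2 <= (0.98 * radius) ** 2
    z = np.sqrt(np.clip(radius**2 - r2, 0.0, None))
    normals = np.stack(
        [np.where(mask, dx / radius, 0.0),
         np.where(mask, dy / radius, 0.0),
         np.where(mask, z / radius, 1.0)],
        axis=-1,
    )
    normals /= np.linalg.norm(normals, axis=-1, keepdims=True)
    return {"mask": mask, "normals": normals, "height": z, "radius": radius,
            "r2": r2}


@pytest.fixture(scope="session")
def hemisphere_stack(hemisphere, rig) -> ImageStack:
    """Noiseless Lambertian render of the hemisphere, albedo 0.5."""
    imgs = np.stack(
        [0.5 * np.clip(hemisphere["normals"] @ L, 0.0, None)
         for L in rig.directions]
    )
    return ImageStack(images=imgs, rig=rig)


@pytest.fixture(scope="session")
def smooth_scene():
    """Smooth noiseless matte blob plus its render (PS round-trip input)."""
    spec = SyntheticSpec(roughness_amp=0.0, irregularity=0.0,
                         specular_strength=0.0, seed=3)
    surface = generate_surface(spec)
    return spec, surface, render_stack(surface, spec, default_rig())


@pytest.fixture(scope="session")
def cohort():
    """Ten-sample firmness gradient (both bands), the demo cohort."""
    return generate_cohort(10, seed=DEMO_SEED)
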