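import pytest
from hypothesis import HealthCheck, settings

from dosemimic.phantom_synth import (
    PhantomSpec,
    default_grid,
    make_phantom_cohort,
    make_template_phantom,
)
from dosemimic.volumes_io import BinaryMask, GridGeometry, ImageVolume

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# coarse grid: same physical extent as the default phantom grid at a
# quarter of the voxel count, for fast registration-heavy tests
COARSE_SHAPE = (48, 48, 24)
COARSE_SPACING = (6.0, 6.0, 10.0)


@pytest.fixture(scope="session")
def coarse_grid() -> GridGeometry:
    return default_grid(COARSE_SHAPE, COARSE_SPACING)


@pytest.fixture(scope="session")
def coarse_template(coarse_grid):
    return make_template_phantom(coarse_grid)


@pytest.fixture(scope="session")
def coarse_spec(coarse_grid):
    return PhantomSpec(grid=coarse_grid, seed=7, dose_style="helical")


@pytest.fixture(scope="session")
def coarse_cohort(coarse_spec):
    return make_phantom_cohort(3, coarse_spec)


@pytest.fixture(scope="session")
def template():
    """Full-resolution template phantom (96x96x48 at 3x3x5 mm)."""
    return make_template_phantom()


def random_dose_and_mask(rng, max_side=20):
    """Small random dose grid and nonempty mask for metric oracles."""
    shape_xyz = tuple(int(rng.integers(4, max_side + 1)) for _ in range(3))
    spacing = tuple(float(rng.uniform(1.0, 5.0)) for _ in range(3))
    geom = GridGeometry(origin=(0.0, 0.0, 0.0), spacing=spacing, shape=shape_xyz)
    dose = ImageVolume(
        geom, rng.uniform(0, 60, size=geom.array_shape), modality="DOSE"
    )
    mask_values = rng.random(geom.array_shape) < 0.5
    if not mask_values.any():
        mask_values.flat[int(rng.integers(mask_values.size))] = True
    mask = BinaryMask(geom, mask_values, name="random")
    return dose, mask
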