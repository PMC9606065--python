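import numpy as np
import pytest

from petsynth.grid import VolumeGrid
from petsynth.phantom import LesionSpec, PhantomSpec, make_pair, make_phantom

#: in-plane/axial spacing of the clinical reconstruction grid (mm, z/y/x)
CLINICAL_SPACING = (3.0, 3.3, 3.3)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """One mid-liver and one skeletal lesion on the small test grid."""
    spacing = CLINICAL_SPACING
    shape = (40, 64, 64)
    extent = [n * s for n, s in zip(shape, spacing)]
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        lesions=[
            LesionSpec(
                organ="liver",
                center_mm=(0.58 * extent[0], 0.50 * extent[1], 0.36 * extent[2]),
                volume_ml=4.0,
                suv=9.0,
            ),
            LesionSpec(
                organ="bones",
                center_mm=(0.80 * extent[0], 0.74 * extent[1], 0.50 * extent[2]),
                volume_ml=1.5,
                suv=7.0,
            ),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_pair(small_spec):
    return make_pair(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def uniform_volume(value: float, shape=(8, 8, 8), spacing=CLINICAL_SPACING) -> VolumeGrid:
    return VolumeGrid(np.full(shape, float(value)), spacing=spacing)
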