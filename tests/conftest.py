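import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from noduletex import (
    CTVolume, PhantomSpec, TextureParams, VesselSpec, generate_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(voxels, spacing=(1.0, 1.0, 1.0), thickness=1.0):
    return CTVolume(np.asarray(voxels, dtype=np.int16), spacing, thickness)


@pytest.fixture
def block_volume():
    """3x3x3 lung background with a 2x2x1 soft-tissue block at 50 HU."""
    voxels = np.full((3, 3, 3), -800, dtype=np.int16)
    voxels[1, 1:3, 1:3] = 50
    return make_volume(voxels)


def benign_spec(seed=0, vessel=False, radius=7.0):
    return PhantomSpec(
        label="benign", center=(24, 24, 24), radius_mm=radius,
        texture=TextureParams(skew=1.5, kurt=3.0, loc_hu=35.0,
                              scale_hu=50.0, body="flat"),
        vessel=VesselSpec(direction=(1.0, 0.3, 0.2)) if vessel else None,
        rng_seed=seed)


def malignant_spec(seed=0, vessel=False, radius=7.0):
    return PhantomSpec(
        label="malignant", center=(24, 24, 24), radius_mm=radius,
        texture=TextureParams(skew=2.0, kurt=6.0, loc_hu=50.0,
                              scale_hu=22.0, body="spike"),
        vessel=VesselSpec(direction=(0.2, 1.0, 0.1)) if vessel else None,
        rng_seed=seed)


@pytest.fixture(scope="session")
def benign_phantom():
    return generate_phantom(benign_spec(seed=11, vessel=True))


@pytest.fixture(scope="session")
def malignant_phantom():
    return generate_phantom(malignant_spec(seed=13))
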