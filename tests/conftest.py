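import numpy as np
import pytest

from brainvox.core import BinaryMask, Volume
from brainvox.phantom import PhantomSpec, make_toy_atlas


@pytest.fixture(scope="session")
def toy_atlas_32():
    return make_toy_atlas((32, 32, 32), n_parents=3, leaves_per_parent=2, voxel_size_um=25.0, seed=1)


@pytest.fixture(scope="session")
def toy_atlas_64():
    return make_toy_atlas((64, 64, 64), n_parents=3, leaves_per_parent=2, voxel_size_um=25.0, seed=1)


NULL_DENSITIES = {"A": {"deep": 800.0, "other": 400.0}, "B": {"deep": 800.0, "other": 400.0}}


def null_spec(seed: int, grid=(64, 64, 64)) -> PhantomSpec:
    """Both groups identical in law: the exchangeable null."""
    return PhantomSpec(grid_shape=grid, plaque_density_per_mm3=NULL_DENSITIES, seed=seed)


def planted_spec(seed: int, grid=(64, 64, 64)) -> PhantomSpec:
    """Default spec: 3x plaque-density excess in deep-layer leaves of group B."""
    return PhantomSpec(grid_shape=grid, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_volume(rng, shape=(8, 8, 8), voxel_size_um=25.0, space="tissue") -> Volume:
    return Volume(rng.normal(size=shape), voxel_size_um, space)


def random_mask(rng, shape=(8, 8, 8), p=0.3, voxel_size_um=25.0, space="tissue") -> BinaryMask:
    return BinaryMask((rng.random(shape) < p).astype(np.uint8), voxel_size_um, space)
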