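import numpy as np
import pytest

from cpcmra import PhantomSpec, VoxelGrid, make_phantom
from cpcmra.meshes import SurfaceModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_tube():
    """Noise-free straight-tube phantom (radius 6 mm, 2 mm grid, 20 frames)."""
    spec = PhantomSpec(noise_sigma=0.0, seed=1)
    dataset, truth = make_phantom(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def noisy_tube():
    """Straight-tube phantom with 5% Rician/Gaussian noise."""
    spec = PhantomSpec(noise_sigma=0.05, seed=1)
    dataset, truth = make_phantom(spec)
    return spec, dataset, truth


def box_mesh(lo, hi) -> SurfaceModel:
    """Watertight axis-aligned box with outward-consistent winding."""
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    v = np.array(
        [
            [lo[0], lo[1], lo[2]], [hi[0], lo[1], lo[2]],
            [hi[0], hi[1], lo[2]], [lo[0], hi[1], lo[2]],
            [lo[0], lo[1], hi[2]], [hi[0], lo[1], hi[2]],
            [hi[0], hi[1], hi[2]], [lo[0], hi[1], hi[2]],
        ]
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
            [0, 1, 5], [0, 5, 4], [2, 3, 7], [2, 7, 6],
            [1, 2, 6], [1, 6, 5], [3, 0, 4], [3, 4, 7],
        ]
    )
    return SurfaceModel(v, f)


@pytest.fixture
def unit_grid():
    return VoxelGrid((16, 16, 16), (1.0, 1.0, 1.0))
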