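import numpy as np
import pytest

from femhead.phantom import LatticeSpec, PhantomSpec, generate
from femhead.volume_io import BinaryVolume


@pytest.fixture(scope="session")
def small_phantom():
    """Small noiseless phantom: 3 mm head at 100 μm voxels (~67³)."""
    spec = PhantomSpec(
        head_radius_um=3000,
        shell_thickness_um=400,
        lattice=LatticeSpec(pitch_um=800, element_thickness_um=250),
        voxel_size_um=100,
        noise_sd=0,
        seed=7,
    )
    vol, truth = generate(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Moderate phantom with noise: 4.8 mm head at 60 μm voxels (~171³)."""
    spec = PhantomSpec(
        head_radius_um=4800,
        shell_thickness_um=600,
        lattice=LatticeSpec(pitch_um=1200, element_thickness_um=300),
        voxel_size_um=60,
        noise_sd=1500,
        seed=3,
    )
    vol, truth = generate(spec)
    return spec, vol, truth


def digital_ball(radius_vox: int, margin: int = 4, voxel_size: float = 100.0) -> BinaryVolume:
    n = 2 * (radius_vox + margin) + 1
    c = n // 2
    ax = np.arange(n) - c
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return BinaryVolume(d2 <= radius_vox**2, voxel_size)


def digital_hemisphere(radius_vox: int, margin: int = 4, voxel_size: float = 100.0) -> BinaryVolume:
    """Upper half-ball (z above the centre voxel, inclusive)."""
    ball = digital_ball(radius_vox, margin, voxel_size)
    c = ball.shape[2] // 2
    data = ball.data.copy()
    data[:, :, :c] = False
    return BinaryVolume(data, voxel_size)
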