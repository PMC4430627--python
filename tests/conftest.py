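import numpy as np
import pytest

from osseoquant import PhantomSpec, generate_phantom
from osseoquant.volume import IMPLANT, LabelVolume

CLEAN = dict(noise_sigma=0.0, blur_sigma=0.0, halo_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_sector_phantom():
    """Noise/blur/halo-free sector phantom, 60-voxel implant diameter."""
    spec = PhantomSpec(
        contact_mode="sector", contact_fraction=0.5, voxel_size=50.0, rng_seed=4, **CLEAN
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_sector_phantom():
    """Sector phantom with the full artifact stack (halo, blur, noise)."""
    spec = PhantomSpec(
        contact_mode="sector", contact_fraction=0.5, voxel_size=50.0, rng_seed=4
    )
    return generate_phantom(spec)


def make_cylinder_labels(radius=40, height=20, spacing=4.0, fill=IMPLANT, pad=3):
    """Axis-aligned digitized cylinder label volume."""
    n = 2 * radius + 2 * pad
    y, x = np.mgrid[:n, :n]
    c = (n - 1) / 2
    circ = (y - c) ** 2 + (x - c) ** 2 <= radius**2
    lab = np.zeros((height, n, n), dtype=np.uint8)
    lab[:, circ] = fill
    return LabelVolume(lab, spacing=spacing)
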