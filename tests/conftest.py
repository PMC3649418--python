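"""Shared fixtures: small phantoms and derived volumes.

Session-scoped where construction is expensive; everything is generated
programmatically and deterministically.
"""
import numpy as np
import pytest

from orthomodel import phantom as ph


@pytest.fixture(scope="session")
def single_tooth_jaw():
    return ph.make_jaw_phantom([ph.ToothPhantomSpec("11")])


@pytest.fixture(scope="session")
def single_tooth_volume(single_tooth_jaw):
    vol, labels = ph.voxelize_phantom(
        single_tooth_jaw, (0.4, 0.4, 0.4),
        ph.IntensityModel(noise_sd=30.0, seed=3))
    return vol, labels


@pytest.fixture(scope="session")
def single_tooth_crown(single_tooth_jaw):
    return single_tooth_jaw.teeth[0].crown_mesh(0.2)


@pytest.fixture(scope="session")
def two_tooth_jaw():
    return ph.make_jaw_phantom(ph.default_arch_specs(2))


@pytest.fixture(scope="session")
def arch_jaw():
    """Three teeth including geometry used by crown-segmentation tests."""
    return ph.make_jaw_phantom(ph.default_arch_specs(3))


@pytest.fixture(scope="session")
def mouth_mesh(arch_jaw):
    return arch_jaw.mouth_mesh(pitch=0.3)


@pytest.fixture(scope="session")
def disk_image():
    """64x64 binary disk (radius 15 at the centre), amplitude chosen so the
    edge-indicator well is informative."""
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.where((xx - 32) ** 2 + (yy - 32) ** 2 <= 15 ** 2, 10.0, 0.0)
    return img
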