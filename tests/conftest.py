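import numpy as np
import pytest

from spheromag.grid import StructuredGrid
from spheromag.magnetics import CylMagnet, ParticleSpec


@pytest.fixture(scope="session")
def table_magnet():
    """Reference magnet at the origin: M_s = 1e6 A/m, R = 0.5 mm, L = 1 mm."""
    return CylMagnet(magnetisation=1e6, radius=0.5e-3, length=1e-3)


@pytest.fixture(scope="session")
def posed_magnet():
    """Reference magnet posed below the chamber (top face 0.25 mm under the wall)."""
    return CylMagnet(
        magnetisation=1e6,
        radius=0.5e-3,
        length=1e-3,
        centre=(1.0e-3, 0.5e-3, -0.75e-3),
    )


@pytest.fixture(scope="session")
def particle():
    """100 nm SPION with D = 2.5e-10 m^2/s and M_sp = 4.78e5 A/m."""
    return ParticleSpec(radius=100e-9, diffusion=2.5e-10, saturation_magnetisation=4.78e5)


@pytest.fixture(scope="session")
def coarse_chamber():
    """Full chamber at 50 um spacing (smoke-test scale)."""
    return StructuredGrid(extents=(2e-3, 1e-3, 1e-3), spacing=50e-6)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
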