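import numpy as np
import pytest

from ctffr.phantom import PhantomSpec, make_vessel_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_spec():
    """Default mid-severity phantom: 30 mm vessel, R0=1.5 mm, d=0.5."""
    return PhantomSpec(
        geometry=make_vessel_geometry(length=30.0, radius=1.5, severity=0.5),
        spacing=(0.5, 0.5, 0.5),
        noise_sd=10.0,
        seed=7,
    )


def sphere_sdf(radius: float, spacing: float, pad: float = 2.5):
    """Signed-distance field of a sphere, positive inside."""
    half = radius + pad
    n = int(np.ceil(2 * half / spacing)) + 1
    c = (n - 1) / 2.0
    z, y, x = np.meshgrid(*[(np.arange(n) - c) * spacing] * 3, indexing="ij")
    return radius - np.sqrt(x**2 + y**2 + z**2)


def torus_sdf(major: float, minor: float, spacing: float = 1.0, pad: float = 2.5):
    half = major + minor + pad
    n = int(np.ceil(2 * half / spacing)) + 1
    c = (n - 1) / 2.0
    z, y, x = np.meshgrid(*[(np.arange(n) - c) * spacing] * 3, indexing="ij")
    return minor - np.sqrt((np.sqrt(x**2 + y**2) - major) ** 2 + z**2)
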