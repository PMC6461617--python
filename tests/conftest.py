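import numpy as np
import pytest

from dnamech.beam import BundleGeometry, MaterialState


@pytest.fixture
def geometry():
    """A mid-range bundle: L = 12 um, d = 100 nm."""
    return BundleGeometry(length=12e-6, diameter=100e-9)


@pytest.fixture
def pristine():
    """Pristine-bundle material state: E = 5.3 GPa, rho = 1700 kg/m3."""
    return MaterialState(young_modulus=5.3e9, density=1700.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
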