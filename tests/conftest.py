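import numpy as np
import pytest

from ringsampler import EnergyPolynomial, ring_readout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bimodal_energy():
    """Double-well U(z) = z^4 - 2 z^2 with modes at +-1."""
    return EnergyPolynomial(1, {(4,): 1.0, (2,): -2.0})


@pytest.fixture
def gaussian_energy():
    """U(z) = z^2 / 2: standard normal."""
    return EnergyPolynomial(1, {(2,): 0.5})


@pytest.fixture
def ring8():
    """Eight decoding columns at evenly spaced angles, unit radius parameter."""
    return ring_readout(8, radius_param=1.0)
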