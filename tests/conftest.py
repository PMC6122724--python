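import numpy as np
import pytest

from mritil import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom case (bias + mild noise), shared across tests."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free phantom: kinetics invert exactly."""
    return make_phantom(PhantomSpec(seed=2, bias_amplitude=0.0, noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
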