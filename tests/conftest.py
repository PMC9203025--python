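import numpy as np
import pytest

from gabafire import EIFKirParams, LIFParams


@pytest.fixture(scope="session")
def lif() -> LIFParams:
    """Standard LIF operating point (tau 20 ms, leak -80, threshold -60 mV)."""
    return LIFParams()


@pytest.fixture(scope="session")
def eif() -> EIFKirParams:
    """Spiny-projection-neuron-like EIF-Kir parameter set."""
    return EIFKirParams()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
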