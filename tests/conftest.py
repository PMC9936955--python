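import numpy as np
import pytest

from sigmer import make_pore_model


@pytest.fixture(scope="session")
def pore4():
    """Small noise-free pore model for exact oracles (4-mer contexts)."""
    return make_pore_model(seed=1, model_k=4, noise_sd=0.0)


@pytest.fixture(scope="session")
def pore6():
    """Default-sized pore model with realistic noise."""
    return make_pore_model(seed=11, model_k=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
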