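import numpy as np
import pytest

from owsr.encoder import EncoderConfig
from owsr.phantom import PhantomSpec, gen_vessel_phantom
from owsr.pipeline import init_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_image():
    """One deterministic 96x96 vessel phantom shared across tests."""
    return gen_vessel_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def tiny_model():
    """Small randomly initialized model (4 blocks, depth 16, M=4)."""
    return init_model(EncoderConfig(n_resblocks=4, n_feats=16), m=4,
                      mlp_hidden=(64, 64), rng=np.random.default_rng(7))
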