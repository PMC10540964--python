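import numpy as np
import pytest

from lungcbir.phantom import PhantomConfig, generate_dataset
from lungcbir.simnet import NetConfig


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(image_size=64, n_slices=20, n_cases=6, seed=3)


@pytest.fixture(scope="session")
def phantom_cases(phantom_config):
    return generate_dataset(phantom_config)


@pytest.fixture(scope="session")
def tiny_net_config():
    """Smallest config the architecture constraints allow; keeps
    gradient-based tests fast."""
    return NetConfig(image_size=32, block_size=8, embed_dim=16, depth=1,
                     heads=2, widths=(4, 8, 8, 8), batch_size=8, epochs=2,
                     seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
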