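import numpy as np
import pytest

import lemmap as lm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """48 images, 64x64, balanced — enough for quick training smoke runs."""
    return lm.generate_dataset(48, image_size=64, seed=101)


@pytest.fixture(scope="session")
def smoke_config():
    return lm.LemConfig(seed=5, max_epochs=3, batch_size=16)


@pytest.fixture(scope="session")
def trained_smoke(small_dataset, smoke_config):
    """A briefly trained network, shared across tests that need one."""
    net, state = lm.train(small_dataset, smoke_config)
    return net, state
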