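import numpy as np
import pytest

import neurodefend as nd


@pytest.fixture(scope="session")
def world():
    return nd.make_world(0)


@pytest.fixture(scope="session")
def encoder(world):
    return nd.ToyEncoder(world)


@pytest.fixture(scope="session")
def small_train(world):
    return nd.sample_dataset(world, 60, "train", 0)


@pytest.fixture(scope="session")
def small_test(world):
    return nd.sample_dataset(world, 20, "test", 0)


@pytest.fixture(scope="session")
def tiny_world():
    """8x8 world: cheap gradients for finite-difference checks."""
    return nd.make_world(3, D=8, H=8, W=8, vocab_size=16)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
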