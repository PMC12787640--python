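import numpy as np
import pytest
from hypothesis import settings

from mambaseg import nn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _seeded_init():
    """Every test builds modules from the same init stream."""
    nn.set_init_seed(0)
    yield


def randomize(module, rng, scale=0.3):
    """Fill every parameter of a module with small random values."""
    for _, p in module.named_parameters():
        p.data[...] = rng.normal(0.0, scale, size=p.data.shape).astype(np.float32)
    return module


def zero_weights(module):
    for _, p in module.named_parameters():
        p.data[...] = 0.0
    return module
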