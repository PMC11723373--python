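import numpy as np
import pytest

from eegnet.synthetic import SynthSpec, gen_tiny_rbm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_rbm():
    """Unpooled 1-kernel 3x3-visible instance with a sample set."""
    return gen_tiny_rbm(seed=3, pool=1)


@pytest.fixture
def tiny_rbm_pooled():
    """Pooled (2x2 block) instance."""
    return gen_tiny_rbm(seed=4, pool=2)


@pytest.fixture
def synth_spec():
    return SynthSpec(seed=7)


@pytest.fixture
def separable_images(rng):
    """Two-class image set that is linearly separable by construction."""
    n, size = 100, 16
    pattern = rng.normal(size=(3, size, size))
    X = rng.normal(size=(n, 3, size, size)) * 0.5
    y = np.repeat([0, 1], n // 2)
    X[y == 1] += 0.8 * pattern
    return X, y
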