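import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """One random 16×16 8-bit image (integer-valued, as float)."""
    return rng.integers(0, 256, size=(16, 16)).astype(float)


def random_images(rng, n, shape=(16, 16)):
    return [rng.integers(0, 256, size=shape).astype(float) for _ in range(n)]
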