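import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_complex_grid(rng):
    def make(h=16, w=16, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return r.normal(size=(h, w)) + 1j * r.normal(size=(h, w))

    return make


@pytest.fixture
def small_phantom():
    from jointmri.phantom import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(size=32), np.random.default_rng(7))
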