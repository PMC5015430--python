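import numpy as np
import pytest

from pcatrack.pcanet import learn_pcanet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_model():
    """A default 2-stage model trained on a handful of random patches."""
    gen = np.random.default_rng(7)
    patches = gen.uniform(size=(10, 32, 32))
    return learn_pcanet(patches)
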