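import numpy as np
import pytest

from emblast import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def small_embedding():
    return synth.random_embedding(20, 16, seed=7, id="small")


@pytest.fixture
def planted_pair():
    """Query/target pair with a 40-residue segment planted at signal 0.7."""
    return synth.make_planted_pair(seed=11)
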