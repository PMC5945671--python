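import numpy as np
import pytest

from scarsig.io import load_packaged_arms, load_packaged_signatures


@pytest.fixture(scope="session")
def sigset():
    return load_packaged_signatures()


@pytest.fixture(scope="session")
def arm_map():
    return load_packaged_arms()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
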