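import numpy as np
import pytest

from scanmap import synthetic as syn


@pytest.fixture(scope="session")
def strip():
    return syn.generate_strip()


@pytest.fixture(scope="session")
def truth(strip):
    return syn.default_truth(strip, seed=11)


@pytest.fixture(scope="session")
def rest_run(strip, truth):
    return syn.generate_rest_run(strip, truth, n_frames=600, tr=1.1, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
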