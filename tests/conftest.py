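import numpy as np
import pytest

from lvtumor import fixtures


@pytest.fixture(scope="session")
def fx():
    return fixtures()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
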