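import numpy as np
import pytest

from dwihist import FULL_SCHEME, IVIM_SCHEME


@pytest.fixture
def rng():
    return np.random.default_rng(20230428)


@pytest.fixture(scope="session")
def full_scheme():
    return FULL_SCHEME


@pytest.fixture(scope="session")
def ivim_scheme():
    return IVIM_SCHEME
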