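import numpy as np
import pytest

from gatedmem import make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ungated_retrieval():
    return make_fixture("ungated_retrieval", seed=7)


@pytest.fixture(scope="session")
def gated_overload():
    return make_fixture("gated_overload", seed=7)


@pytest.fixture(scope="session")
def orthogonal_pair_fixture():
    return make_fixture("orthogonal_pair", seed=7)
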