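import numpy as np
import pytest

from broncholoc.synthesis import standard_fixture


@pytest.fixture(scope="session")
def slow_stable():
    return standard_fixture("slow_stable")


@pytest.fixture(scope="session")
def sudden_jump():
    return standard_fixture("sudden_jump")


@pytest.fixture(scope="session")
def glare_heavy():
    return standard_fixture("glare_heavy")


@pytest.fixture(scope="session")
def straight_tube():
    return standard_fixture("straight_tube")


@pytest.fixture(scope="session")
def tree_g3():
    return standard_fixture("tree_g3")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
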