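import numpy as np
import pytest

from iftirt import ThetaGrid, make_fixture_suite, rh_table1_itemset

SUITE_SEED = 1234


@pytest.fixture(scope="session")
def default_grid():
    return ThetaGrid.regular()


@pytest.fixture(scope="session")
def coarse_grid():
    return ThetaGrid.regular(-4, 4, 0.05)


@pytest.fixture(scope="session")
def fixture_suite():
    return make_fixture_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def table1_items():
    return rh_table1_itemset()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
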