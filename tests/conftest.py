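import numpy as np
import pandas as pd
import pytest

from fuzzcomfa import field_engine, fixtures

ADR_WEIGHTS = {"3IP9": 0.50, "3N8V": 0.40, "2L0W": 0.10}


@pytest.fixture(scope="session")
def table1():
    return fixtures.table1_fixture()


@pytest.fixture(scope="session")
def docking_scores(table1):
    return table1[["3IP9", "3N8V", "2L0W"]]


@pytest.fixture(scope="session")
def table4():
    return fixtures.table4_fixture()


@pytest.fixture(scope="session")
def table5():
    return fixtures.table5_fixture()


@pytest.fixture(scope="session")
def table6():
    return fixtures.table6_fixture()


@pytest.fixture(scope="session")
def synthetic_default():
    """Default-condition synthetic series with its descriptor table."""
    mols, y = fixtures.synthetic_series()
    grid = field_engine.make_grid(mols)
    blocks = [field_engine.compute_field_block(m, grid) for m in mols]
    table = field_engine.assemble_descriptor_table(blocks, y)
    return mols, y, table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_linear_data(rng):
    """Tiny exactly linear regression instance: y = X @ b, no noise."""
    X = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
    b = np.array([1.0, -2.0, 0.5, 0.0])
    y = pd.Series(X.to_numpy() @ b, index=X.index)
    return X, y, b
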