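import pytest

from mshrs import PeriodModel, load_valuation


@pytest.fixture(scope="session")
def valuation():
    """Default 2011 German valuation config: (tables, dmt_table, adjustment)."""
    return load_valuation()


@pytest.fixture(scope="session")
def tables(valuation):
    return valuation[0]


@pytest.fixture(scope="session")
def dmt_table(valuation):
    return valuation[1]


@pytest.fixture(scope="session")
def adj(valuation):
    return valuation[2]


@pytest.fixture(scope="session")
def labor(tables):
    return tables.labor


@pytest.fixture(scope="session")
def period():
    return PeriodModel()
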