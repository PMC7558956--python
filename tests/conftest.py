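import pytest

from gutfa import load_fixture_tables


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def drugs(tables):
    return tables[0]


@pytest.fixture(scope="session")
def physiology(tables):
    return tables[1]


@pytest.fixture(scope="session")
def scenarios(tables):
    return tables[2]
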