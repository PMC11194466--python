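import pytest

from crcprev import default_parameters, make_life_table, standard_strategies


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life():
    return make_life_table()


@pytest.fixture(scope="session")
def strategies():
    return standard_strategies()
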