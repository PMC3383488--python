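import pytest

from ptsd_cea import load_parameters, default_strategies


@pytest.fixture(scope="session")
def params():
    """The shipped default parameter configuration."""
    return load_parameters()


@pytest.fixture(scope="session")
def strategies(params):
    return default_strategies(params)


@pytest.fixture(scope="session")
def strategy_map(strategies):
    return {s.name: s for s in strategies}
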