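import pytest

from btc_cea.cli import default_config, default_ranges
from btc_cea.parameters import load_parameters
from btc_cea.sensitivity import load_ranges


@pytest.fixture(scope="session")
def bt22():
    """Packaged trial fixture: (ParameterSet, list of DistributionSpec)."""
    return load_parameters(default_config())


@pytest.fixture(scope="session")
def params(bt22):
    return bt22[0]


@pytest.fixture(scope="session")
def specs(bt22):
    return bt22[1]


@pytest.fixture(scope="session")
def dsa_ranges():
    return load_ranges(default_ranges())
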