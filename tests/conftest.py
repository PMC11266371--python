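import pytest
from hypothesis import settings

from bbmcue import ParameterSet, default_fixture_bundle

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params_text() -> ParameterSet:
    return ParameterSet.default("text")


@pytest.fixture(scope="session")
def params_table1() -> ParameterSet:
    return ParameterSet.default("table1")


@pytest.fixture(scope="session")
def f0():
    return default_fixture_bundle()
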