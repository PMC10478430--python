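import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1_calls():
    from metconcord.io import table1_mutation_calls
    return table1_mutation_calls()


@pytest.fixture(scope="session")
def table2():
    from metconcord.io import load_fixture
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    from metconcord.io import load_fixture
    return load_fixture("table3")
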