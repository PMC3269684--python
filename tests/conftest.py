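import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def table():
    from wheyfrac import load_experiment_table
    return load_experiment_table()


@pytest.fixture(scope="session")
def catalog():
    from wheyfrac import load_equipment_catalog
    return load_equipment_catalog()


@pytest.fixture(scope="session")
def econ():
    from wheyfrac import EconomicModel
    return EconomicModel()
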