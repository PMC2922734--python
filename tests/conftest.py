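import pytest
from hypothesis import HealthCheck, settings

from lagcost import (NORSTROM_PARAMS, SWEDISH_COST_CONFIG, WOMEN_TABLE1,
                     build_schedule, run_counterfactual)

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def women():
    return WOMEN_TABLE1


@pytest.fixture(scope="session")
def schedule10():
    return build_schedule(NORSTROM_PARAMS, 10)


@pytest.fixture(scope="session")
def schedule24():
    return build_schedule(NORSTROM_PARAMS, 24)


@pytest.fixture(scope="session")
def women_series10(women, schedule10):
    return run_counterfactual(women, schedule10)


@pytest.fixture(scope="session")
def cost_config():
    return SWEDISH_COST_CONFIG
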