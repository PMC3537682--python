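import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from spatmotif import build_domain
from spatmotif.scenarios import execute_scenario

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scenario_cache():
    """Memoized scenario runs: several tests interrogate the same (expensive)
    trajectory, so each scenario executes at most once per session."""
    cache = {}

    def run(scenario_id):
        if scenario_id not in cache:
            cache[scenario_id] = execute_scenario(scenario_id)
        return cache[scenario_id]

    return run


@pytest.fixture
def domain():
    return build_domain(200)


@pytest.fixture
def small_domain():
    return build_domain(64)


@pytest.fixture
def cosine_signal(domain):
    return 1.0 + 0.5 * np.cos(domain.theta)
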