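import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from inclusion_monitor.indicator_engine import default_indicator_configs
from inclusion_monitor.synthetic_data import default_scenario


@pytest.fixture(scope="session")
def configs():
    return default_indicator_configs()


@pytest.fixture(scope="session")
def small_population():
    """One deterministic medium-size synthetic population, shared across tests."""
    from inclusion_monitor.synthetic_data import generate_population

    scenario = default_scenario(n_respondents=2000, seed=424242)
    return scenario, generate_population(scenario)
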