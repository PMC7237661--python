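import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import physep as pp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg() -> pp.CohortConfig:
    return pp.default_config(seed=20_200_519)


@pytest.fixture(scope="session")
def default_trials(default_cfg) -> pd.DataFrame:
    """One standard 100-participant cohort shared across tests."""
    _, trials = pp.simulate_cohort(default_cfg)
    return trials


@pytest.fixture(scope="session")
def default_scores(default_trials) -> pd.DataFrame:
    screen = pp.screen_participants(default_trials)
    return pp.score_primary(pp.apply_screen(default_trials, screen))
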