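import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_generator_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*clamped.*")
        yield


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic cohort, shared across read-only tests."""
    from trialcea import trial_data as td

    return td.generate_trial(td.SyntheticTrialConfig(seed=1))


@pytest.fixture(scope="session")
def price_table():
    from trialcea import costing

    return costing.default_price_table()


@pytest.fixture(scope="session")
def friction():
    from trialcea import costing

    return costing.FrictionParams()
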