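import numpy as np
import pytest

from chronobeh import GenConfig, simulate_two_interval_session, simulate_fixed_interval_session
from chronobeh.lever_events import detect_session


def noise_free_config(**overrides):
    """Config with all stochastic terms collapsed (weber must stay > 0)."""
    base = dict(
        weber_fraction=1e-9,
        coordination_noise=0.0,
        position_jitter_cm=0.0,
        attempt_failure_rate=0.0,
        reactive_release_fraction=0.0,
        lapse_coefficient=0.0,
        n_trials=30,
    )
    base.update(overrides)
    return GenConfig(**base)


@pytest.fixture(scope="session")
def clean_config():
    return noise_free_config()


@pytest.fixture(scope="session")
def default_config():
    return GenConfig(n_trials=60)


@pytest.fixture(scope="session")
def clean_two_interval(clean_config):
    """Noise-free two-interval session plus its detection output."""
    session = simulate_two_interval_session(clean_config, 0.0, seed=11)
    return session, detect_session(session)


@pytest.fixture(scope="session")
def clean_fixed_interval(clean_config):
    session = simulate_fixed_interval_session(clean_config, 0.0, seed=11)
    return session, detect_session(session)


@pytest.fixture(scope="session")
def noisy_two_interval(default_config):
    session = simulate_two_interval_session(default_config, 0.0, seed=21)
    return session, detect_session(session)
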