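import dataclasses

import pytest

from metcal import default_config, generate_cohort, steady_state_table


@pytest.fixture(scope="session")
def config():
    return default_config(seed=7)


@pytest.fixture(scope="session")
def cohort(config):
    return generate_cohort(config)


@pytest.fixture(scope="session")
def steady(cohort):
    return steady_state_table(cohort)


@pytest.fixture(scope="session")
def zero_noise_config(config):
    """Fully deterministic cohort: no count, MET or participant variation."""
    profiles = tuple(
        dataclasses.replace(p, ap_count_sd=0.0, ag_count_sd=0.0, met_sd=0.0)
        for p in config.profiles
    )
    return config.replace(
        profiles=profiles,
        residual_met_sd=0.0,
        participant_intercept_sd=0.0,
        participant_slope_sd=0.0,
        posture_transition_latency=0,
    )


@pytest.fixture(scope="session")
def equal_minutes_config(config):
    """Protocol variant with equal sitting/standing/slow-walking durations."""
    profiles = tuple(
        dataclasses.replace(p, duration_min=5.0)
        if p.label in ("sit", "stand", "slow_walk")
        else p
        for p in config.profiles
    )
    return config.replace(profiles=profiles)
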