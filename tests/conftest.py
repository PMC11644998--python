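"""Shared fixtures: small synthetic cohorts and handcrafted series."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tibload.biomech import day_insole_ls
from tibload.config import CohortConfig, RunConfig
from tibload.datatypes import InsoleSeries, ParticipantMeta, TibiaForceSeries
from tibload.models import fit_generic
from tibload.synthetic import generate_cohort

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort (3 participants, ~5 h days) and a sparse window
    schedule, sized for fast unit tests."""
    return RunConfig(
        window_increment_min=60,
        stride_min=150,
        cohort=CohortConfig(n_participants=3, day_minutes_min=300, day_minutes_max=330),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def small_insole_ls(small_config, small_cohort):
    return {d.participant_id: day_insole_ls(d, small_config) for d in small_cohort}


@pytest.fixture(scope="session")
def small_model_set(small_config, small_cohort, small_insole_ls):
    return fit_generic(small_cohort, config=small_config, seed=11, insole_ls=small_insole_ls)


@pytest.fixture(scope="session")
def noise_free_config():
    return RunConfig(cohort=CohortConfig.noise_free_linear(n_participants=2))


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_config):
    return generate_cohort(noise_free_config, seed=3)


@pytest.fixture
def toy_meta():
    return ParticipantMeta(
        participant_id="T01",
        body_mass=70.0,
        ankle_offset_x=0.05,
        achilles_moment_arm_r=0.05,
        insole_length=0.26,
    )


def constant_force_minute(value_bw: float, rate: float = 25.0, n_minutes: int = 1):
    """Tibia-force series constant at ``value_bw`` over whole minutes,
    including the closing boundary sample."""
    n = int(round(n_minutes * 60 * rate)) + 1
    t = np.arange(n) / rate
    return TibiaForceSeries(t=t, f_tibia=np.full(n, value_bw), sample_rate=rate)


@pytest.fixture
def make_constant_minute():
    return constant_force_minute


@pytest.fixture
def tiny_insole():
    """Three-sample insole series with a single loaded sample."""
    return InsoleSeries(
        t=np.array([0.0, 0.04, 0.08]),
        force=np.array([0.0, 700.0, 0.0]),
        cop=np.array([0.15, 0.15, 0.15]),
        sample_rate=25.0,
    )
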