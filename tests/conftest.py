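import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import apdscreen as a

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return a.default_config(seed=0)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """One frozen synthetic study-size cohort (14 cases / 19 controls)."""
    from apdscreen.synthetic import with_seed

    return a.sample_cohort(with_seed(default_config, 42))


@pytest.fixture(scope="session")
def small_params(small_cohort):
    return a.derive_cohort(small_cohort)


def make_week(
    patient_id="p1",
    group=a.CASE,
    alarms=(1, 2, 0, 3, 1, 0, 2),
    drain_times=(20.0,) * 7,
    lastfill_fill=1000.0,
    lastfill_drains=(990.0,) * 7,
    cycler_fill=9500.0,
    cycler_drains=(9600.0,) * 7,
    glucose=124.1,
):
    """Hand-built patient week for unit tests."""
    sessions = tuple(
        a.CyclerSession(
            patient_id=patient_id,
            day_index=d + 1,
            n_alarms=alarms[d],
            final_drain_time_min=drain_times[d],
            cycler_fill_ml=cycler_fill,
            cycler_drain_ml=cycler_drains[d],
            lastfill_fill_ml=lastfill_fill,
            lastfill_drain_ml=lastfill_drains[d] if lastfill_fill > 0 else 0.0,
            glucose_load_g=glucose,
        )
        for d in range(7)
    )
    return a.PatientWeek(patient_id=patient_id, group=group, sessions=sessions)


@pytest.fixture
def toy_week():
    return make_week()


@pytest.fixture
def rng():
    return np.random.default_rng(123)
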