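import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cachetraj import CohortSpec, PatientSeries, generate_cohort  # noqa: E402


def make_series(patient_id="P0", pre=((-30, 80.0),), post=((0, 80.0), (30, 78.0)),
                bmi=25.0, os_time=365, os_event=1, channels=None,
                true_archetype=None):
    """Compact PatientSeries constructor for hand-built examples.

    ``pre``/``post`` are (time_days, weight_kg) pairs; ``bmi`` is either a
    scalar applied to every measurement or a (pre_list, post_list) pair.
    """
    pre = list(pre)
    post = list(post)
    if np.isscalar(bmi):
        pre_bmi = [bmi] * len(pre)
        post_bmi = [bmi] * len(post)
    else:
        pre_bmi, post_bmi = bmi
    if channels is None:
        channels = {"overall": (os_time, os_event)}
    return PatientSeries(
        patient_id=patient_id,
        pre_times=np.array([t for t, _ in pre], int),
        pre_weights=np.array([w for _, w in pre], float),
        pre_bmis=np.asarray(pre_bmi, float),
        post_times=np.array([t for t, _ in post], int),
        post_weights=np.array([w for _, w in post], float),
        post_bmis=np.asarray(post_bmi, float),
        event_channels=channels,
        true_archetype=true_archetype,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (seed 1), shared across tests."""
    return generate_cohort(CohortSpec())


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 150-patient cohort for pipeline-level tests."""
    return generate_cohort(CohortSpec(n_patients=150, seed=7))
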