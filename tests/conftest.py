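import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petquant import (CohortSpec, FrameSchedule, default_schedule, make_cohort,
                      make_roi_phantom, simulate_blood)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return default_schedule()


@pytest.fixture(scope="session")
def fit_schedule(schedule) -> FrameSchedule:
    """The post-injection frames only (background frame dropped)."""
    m = schedule.post_injection_mask()
    return FrameSchedule(schedule.start[m], schedule.duration[m],
                         schedule.injection_offset)


@pytest.fixture(scope="session")
def cohort_spec() -> CohortSpec:
    return CohortSpec(n_participants=20, seed=7)


@pytest.fixture(scope="session")
def noisefree_spec() -> CohortSpec:
    return CohortSpec(n_participants=20, seed=7, blood_noise=0.0,
                      parent_fraction_noise=0.0, dynamic_noise=0.0)


@pytest.fixture(scope="session")
def metas(cohort_spec):
    return make_cohort(cohort_spec)


@pytest.fixture(scope="session")
def noisefree_blood(metas, noisefree_spec):
    """(continuous, discrete, true input function) without measurement noise."""
    return simulate_blood(metas[0], noisefree_spec, seed=123)


@pytest.fixture(scope="session")
def true_if(noisefree_blood):
    return noisefree_blood[2]


@pytest.fixture(scope="session")
def tiny_phantom():
    """Seven single-voxel regions in a 6x6x6 volume: fast voxelwise fits."""
    return make_roi_phantom((6, 6, 6))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
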