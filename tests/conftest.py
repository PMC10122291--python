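import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ambicox import SimConfig, SubjectRecord, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_records():
    """Hand-built four-case cohort: one subject per design configuration."""
    return [
        # Case 1: responded, no recurrence, followed to the recontact at 12 y
        SubjectRecord("case1", sex=1, age_first_vt=40.0, provoked_first_vt=0,
                      dvt_first_vt=1, t_inclusion=5.0, t_collection=12.0,
                      responded_recontact=1, vital_status="alive", t_last_vital=12.0),
        # Case 2: responded, recurrence between inclusion and collection
        SubjectRecord("case2", sex=0, age_first_vt=50.0, provoked_first_vt=1,
                      dvt_first_vt=0, t_inclusion=5.0, recurrence_observed=1,
                      t_recurrence=8.0, t_collection=12.0, responded_recontact=1,
                      vital_status="alive", t_last_vital=12.0),
        # Case 3: lost to follow-up at recontact
        SubjectRecord("case3", sex=1, age_first_vt=35.0, provoked_first_vt=1,
                      dvt_first_vt=1, t_inclusion=5.0, t_collection=5.0,
                      responded_recontact=0, vital_status="dead", t_last_vital=9.0),
        # Case 4: recurrence before inclusion
        SubjectRecord("case4", sex=0, age_first_vt=45.0, provoked_first_vt=0,
                      dvt_first_vt=0, t_inclusion=5.0, recurrence_observed=1,
                      t_recurrence=3.0, t_collection=5.0, responded_recontact=0,
                      vital_status="alive", t_last_vital=11.0),
    ]


@pytest.fixture(scope="session")
def sim_cohort():
    """Moderate synthetic cohort with observed mortality, shared read-only
    across tests."""
    cfg = SimConfig(n_subjects=800, seed=42, gompertz_rate=2e-4, p_vital_known=1.0)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
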