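import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sitbdetect.synthetic_ehr import CohortConfig, generate_cohort, cohort_to_frame


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 400-encounter cohort shared across tests."""
    cfg = CohortConfig(n_encounters=400, seed=123)
    encounters, notes = generate_cohort(cfg)
    return cfg, encounters, notes


@pytest.fixture(scope="session")
def small_cohort_frame(small_cohort):
    _, encounters, _ = small_cohort
    return cohort_to_frame(encounters)


@pytest.fixture(scope="session")
def notes_by_encounter(small_cohort):
    _, _, notes = small_cohort
    by_enc = {}
    for n in notes:
        by_enc.setdefault(n.encounter_id, []).append(n)
    return by_enc


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
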