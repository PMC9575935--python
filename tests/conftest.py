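import numpy as np
import pytest

from kdtriage import CohortTable, CriteriaSet, Diagnosis, LabPanel, PatientRecord
from kdtriage.simulate import default_spec, generate


def make_record(
    rid,
    diagnosis=Diagnosis.KD,
    criteria=(True, True, True, True, False),
    illness_days=5,
    age_years=1.5,
    **labs,
):
    return PatientRecord(
        id=rid,
        diagnosis=diagnosis,
        criteria=CriteriaSet(*criteria),
        illness_days=illness_days,
        age_years=age_years,
        labs=LabPanel(**labs),
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """120 KD + 120 FC synthetic records, fixed seed."""
    return generate(default_spec(n_kd=120, n_fc=120, seed=7))


@pytest.fixture(scope="session")
def medium_cohort() -> CohortTable:
    """400/group synthetic cohort for pipeline tests."""
    return generate(default_spec(n_kd=400, n_fc=400, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
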