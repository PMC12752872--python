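from datetime import date

import pytest

from amskit import generate_cohort, load_formulary
from amskit.records import DoseModel, MedicationCourse


@pytest.fixture(scope="session")
def formulary():
    return load_formulary()


@pytest.fixture(scope="session")
def small_cohort():
    """50 synthetic patients, fixed seed, shared read-only across tests."""
    return generate_cohort(n_patients=50, seed=2024)


def make_course(drug_id, dose, unit, freq=1.0, period=30.0,
                start=date(2023, 1, 1)):
    return MedicationCourse(
        drug_id=drug_id,
        dose_per_administration=DoseModel(value=dose, unit=unit),
        frequency_per_day=freq,
        period_days=period,
        start_date=start,
    )
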