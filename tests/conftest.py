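from datetime import datetime, timedelta

import numpy as np
import pytest

from pabgram.cohort import (
    CultureResult,
    GeneratorConfig,
    PatientInfection,
    generate_cohort,
)

PT = datetime(2019, 6, 1, 12, 0, 0)


def make_infection(
    cultures,
    infection_id="I0",
    prediction_time=PT,
    coded_events=(),
    numeric_events=(),
    administrations=(),
    clinician_selection="ceftriaxone",
    infection_icd_flag=False,
    died=False,
    year=2019,
    **kwargs,
):
    """Minimal admission for unit tests of labeling / phenotype / features."""
    return PatientInfection(
        patient_id="P0",
        infection_id=infection_id,
        year=year,
        prediction_time=prediction_time,
        age_years=kwargs.pop("age_years", 60.0),
        sex=kwargs.pop("sex", "Female"),
        race=kwargs.pop("race", "White"),
        ethnicity=kwargs.pop("ethnicity", "Non-Hispanic"),
        insurance=kwargs.pop("insurance", "Medicare"),
        institution=kwargs.pop("institution", "Academic ED"),
        coded_events=list(coded_events),
        numeric_events=list(numeric_events),
        cultures=list(cultures),
        clinician_selection=clinician_selection,
        antibiotics_administered=list(administrations),
        infection_icd_flag=infection_icd_flag,
        died_during_admission=died,
        **kwargs,
    )


def culture(organism, calls=None, culture_type="urine"):
    return CultureResult(culture_type, organism, calls or {})


def days_ago(n, hours=0):
    return PT - timedelta(days=n, hours=hours)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_patients=900, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def assert_feasible(allocation, budgets):
    """Feasibility/integrality contract shared across allocation tests."""
    S = allocation.matrix
    assert set(np.unique(S)) <= {0, 1}
    assert (S.sum(axis=1) == 1).all()
    assert np.array_equal(S.sum(axis=0), np.asarray(budgets))
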