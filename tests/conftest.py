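import numpy as np
import pandas as pd
import pytest

from ndrpath import (
    CohortParams,
    PatientProfile,
    default_coefficients,
    generate_cohort,
)


@pytest.fixture(scope="session")
def coeffs():
    return default_coefficients()


@pytest.fixture(scope="session")
def low_risk_profile():
    """Nonsmoking woman, 60 years and BMI 27 at diagnosis, mean baselines."""
    return PatientProfile(
        age_at_diagnosis=60, female=True, smoker_at_diagnosis=False,
        hba1c=7.00, sbp=138.00, bmi=27.00, tchdl=4.50, ldl=3.00,
    )


@pytest.fixture(scope="session")
def high_risk_profile():
    """Smoking man, 60 years and BMI 32 at diagnosis, mean baselines."""
    return PatientProfile(
        age_at_diagnosis=60, female=False, smoker_at_diagnosis=True,
        hba1c=7.00, sbp=138.00, bmi=32.00, tchdl=4.50, ldl=3.00,
    )


def noise_free_params(n=20, seed=None, **overrides):
    """Cohort parameters with every stochastic disturbance switched off."""
    defaults = dict(
        n=n,
        diagnosis_years=(2001, 2004),
        follow_up_end=2008,
        sigma_mu={rf: 0.0 for rf in ("hba1c", "sbp", "tchdl", "ldl", "bmi")},
        sigma_nu={rf: 0.0 for rf in ("hba1c", "sbp", "tchdl", "ldl", "bmi")},
        annual_dropout=0.0,
        visit_missingness=0.0,
        baseline_missingness=0.0,
        smoking_unchanged_smoker=1.0,
        smoking_unchanged_nonsmoker=1.0,
    )
    defaults.update(overrides)
    return CohortParams(**defaults)


@pytest.fixture(scope="session")
def noise_free_panel():
    return generate_cohort(noise_free_params(n=20), seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noisy balanced cohort shared by estimation tests."""
    params = CohortParams(
        n=400, diagnosis_years=(2001, 2001), follow_up_end=2008,
        annual_dropout=0.0, visit_missingness=0.0, baseline_missingness=0.0,
    )
    return generate_cohort(params, seed=11)


@pytest.fixture()
def toy_panel():
    """Three patients, hand-written values, for differencing/inclusion tests."""
    rows = []
    for pid, series in {
        1: [(1, 7.0), (2, 6.5), (3, 6.5)],        # consecutive
        2: [(1, 5.0), (3, 6.0)],                  # gap at t=2
        3: [(2, 4.0)],                            # single observation
    }.items():
        for t, v in series:
            rows.append({
                "patient_id": pid, "duration": t, "hba1c": v,
                "year_of_diagnosis": 2001, "calendar_year": 2001 + t,
                "age_at_diagnosis": 55.0, "female": 0, "smoking": 0.0,
                "treatment_class": "diet", "sbp": 140.0, "bmi": 30.0,
                "tchdl": 4.0, "ldl": 3.0,
            })
    return pd.DataFrame(rows)
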