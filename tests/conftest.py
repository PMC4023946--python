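import numpy as np
import pandas as pd
import pytest

from ssiml.synthetic_cohort import SyntheticConfig, CohortTable, generate_cohort


def make_cohort(
    n_hospitals=10,
    wards_per_hospital=2,
    patients_per_ward=30,
    intercept=-2.0,
    ward_var=0.5,
    slope_cov=(0.0, 0.0),
    hospital_variance=0.0,
    beta=None,
    prevalences=None,
    seed=0,
) -> CohortTable:
    """Small synthetic cohort helper for unit tests."""
    cfg = SyntheticConfig(
        n_hospitals=n_hospitals,
        wards_per_hospital=wards_per_hospital,
        patients_per_ward=patients_per_ward,
        covariate_prevalences=prevalences or {},
        beta=beta or {},
        intercept=intercept,
        ward_covariance=(ward_var, slope_cov[0], slope_cov[1]),
        hospital_variance=hospital_variance,
        seed=seed,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort() -> CohortTable:
    """10 hospitals x 2 wards x 30 patients, moderate outcome prevalence."""
    return make_cohort(
        seed=7,
        prevalences={"asa_gt2": 0.3, "gender_female": 0.5, "followup_ge15": 0.6},
        beta={"asa_gt2": 0.6},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def records_cohort(rows: list[dict]) -> CohortTable:
    """Cohort from explicit records, filling unset fields."""
    from ssiml.synthetic_cohort import COLUMNS, BINARY_COVARIATES

    df = pd.DataFrame(rows)
    for c in COLUMNS:
        if c not in df.columns:
            if c in ("duration_minutes", "followup_days"):
                df[c] = np.nan
            elif c == "procedure_type":
                df[c] = "gastrointestinal"
            elif c in BINARY_COVARIATES or c == "ssi":
                df[c] = 0
            else:
                raise AssertionError(c)
    for c in ("ssi",) + BINARY_COVARIATES:
        df[c] = df[c].astype("Int64")
    return CohortTable(df[list(COLUMNS)])
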