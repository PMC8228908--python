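import numpy as np
import pytest

from ccwtmle import (
    CohortSpec,
    ConfounderSpec,
    default_cohort_spec,
    generate_cohort,
    sample_case_control,
)


@pytest.fixture(scope="session")
def one_binary_spec():
    """Single binary confounder; everything is enumerable by hand."""
    return CohortSpec(
        n_cohort=60_000,
        age_distribution={"40-44": 1.0},
        confounders=(ConfounderSpec("w1", "binary", {"p": 0.4}),),
        exposure_coefficients={"intercept": -0.3, "w1": 0.8},
        outcome_coefficients={"intercept": -4.0, "exposure": 0.6, "w1": 0.7},
        seed=3,
    )


@pytest.fixture(scope="session")
def one_binary_sample(one_binary_spec):
    cohort = generate_cohort(one_binary_spec)
    return sample_case_control(cohort, 400, 900, seed=5)


@pytest.fixture(scope="session")
def study_sample():
    """Default study conditions: 787 cases / 928 controls from 100k cohort."""
    cohort = generate_cohort(default_cohort_spec(seed=42))
    return sample_case_control(cohort, 787, 928, seed=7)


@pytest.fixture(scope="session")
def study_confounders():
    return ["age_z", "educ", "w_cont", "urban"]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
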