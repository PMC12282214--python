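import numpy as np
import pytest

from actibreak.config import (CohortConfig, ImputationSpec, MissingnessConfig,
                              StudyConfig)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def no_missingness() -> MissingnessConfig:
    zero = (0.0, 0.0)
    return MissingnessConfig(accel=zero, age=zero, sex=zero, bmi=zero,
                             manager=zero, k6=zero, uwes=zero, hpq=zero,
                             adherence=0.0, attrition=zero)


@pytest.fixture
def clean_cohort_config():
    """Default calibration, reduced wear days, no missing data."""
    return CohortConfig(seed=11, wear_days_override=5,
                        missingness=no_missingness())


@pytest.fixture
def small_study_config(clean_cohort_config):
    return StudyConfig(cohort=clean_cohort_config,
                       imputation=ImputationSpec(m=2, seed=11),
                       outcomes=("sb", "k6"), complete_case=True, seed=11)
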