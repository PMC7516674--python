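import numpy as np
import pytest

from hypnohrv.prediction import build_feature_table
from hypnohrv.synthetic import CohortEffectConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hrv_effect_features():
    """Feature table of a cohort whose groups differ only in RR-generator
    parameters (clinical covariates drawn from identical distributions).

    Shared by the prediction tests: clinical-only models should be at
    chance on it, full-feature models well above.
    """
    cfg = CohortEffectConfig.hrv_only_effects(n_cases=60, n_controls=60,
                                              seed=21, duration=900.0)
    return build_feature_table(generate_cohort(cfg))


@pytest.fixture(scope="session")
def study_effect_cohort():
    """Small cohort with clinical and HRV effects in the published directions."""
    cfg = CohortEffectConfig.study_effects(n_cases=40, n_controls=200,
                                           seed=3, duration=600.0)
    return generate_cohort(cfg)
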