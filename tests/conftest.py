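"""Shared fixtures: a default configuration and calibrated models.

Calibration is done once per session on a 100,000-subject sample with fixed
seeds, so every test sees the same generator.
"""

import numpy as np
import pytest

import survimpute as si


@pytest.fixture(scope="session")
def cfg():
    return si.default_config()


@pytest.fixture(scope="session")
def calibrator(cfg):
    return si.Calibrator(cfg, calib_n=100_000)


@pytest.fixture(scope="session")
def surv30(calibrator):
    """Survival model with censoring calibrated to the 30% level."""
    return calibrator.survival_for(0.30)


@pytest.fixture(scope="session")
def small_cohort(cfg, surv30):
    """One n=400 cohort at the higher censoring level."""
    spec = si.ScenarioSpec(n=400, censor_target=0.30, miss_target=0.10, seed=11)
    return si.simulate_complete(spec, cfg.covariates, surv30, seed=11)


@pytest.fixture(scope="session")
def incomplete_cohort(cfg, calibrator, small_cohort):
    """The small cohort with calibrated 10% MAR gaps."""
    spec = calibrator.missingness_for(0.30, 0.10)
    return si.apply_missingness(small_cohort, spec, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


#: fast tuning settings used wherever a test exercises the expensive methods
FAST_TUNING = dict(cv_folds=3,
                   svm_c_grid=[0.5, 8.0], svm_gamma_grid=[0.01, 0.25],
                   rf_trees=60, rf_mtry_grid=[3, 6], lasso_n_alphas=20)


@pytest.fixture(scope="session")
def fast_tuning():
    return dict(FAST_TUNING)
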