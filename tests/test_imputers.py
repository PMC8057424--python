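"""Imputation tests: design assembly, method fits, noise rules, completion."""

import numpy as np
import pandas as pd
import pytest

import survimpute as si
from survimpute.imputers import _child_seed
from survimpute.survival import CumHazCurve, EstimationError


@pytest.fixture(scope="module")
def curve(incomplete_cohort):
    frame = incomplete_cohort.to_frame()
    fit = si.fit_cox(frame, incomplete_cohort.complete_columns())
    return si.baseline_cumhaz(fit, frame, "KP")


@pytest.fixture(scope="module")
def hgb_design(incomplete_cohort, curve):
    return si.build_design(incomplete_cohort, curve, "HGB")


def linear_design(design, weights=None, intercept=1.0):
    """Copy of a design whose response is an exact linear function of W."""
    from dataclasses import replace
    W = design.W.to_numpy(float)
    if weights is None:
        weights = np.linspace(-0.5, 0.5, W.shape[1])
    y = intercept + W @ weights
    return replace(design, y=y), y


class TestBuildDesign:
    def test_thirteen_predictor_columns(self, hgb_design):
        # 10 complete baseline covariates + ARM + delta + cumulative hazard
        assert hgb_design.W.shape[1] == 13
        assert "delta" in hgb_design.W.columns and "cumhaz" in hgb_design.W.columns
        for other in ("PROG", "LALP", "HGB"):
            assert other not in hgb_design.W.columns
        assert not hgb_design.W.isna().any().any()

    def test_row_partition(self, incomplete_cohort, hgb_design):
        n = incomplete_cohort.n
        assert len(hgb_design.observed_rows) + len(hgb_design.missing_rows) == n
        assert not set(hgb_design.observed_rows) & set(hgb_design.missing_rows)

    def test_all_censored_cohort_gives_zero_survival_columns(self, incomplete_cohort):
        from dataclasses import replace
        toy = replace(incomplete_cohort, delta=np.zeros(incomplete_cohort.n, dtype=int))
        empty = CumHazCurve(times=np.array([]), H=np.array([]), estimator_tag="KP")
        design = si.build_design(toy, empty, "HGB")
        assert not design.W["delta"].any()
        assert not design.W["cumhaz"].any()

    def test_unknown_target_rejected(self, incomplete_cohort, curve):
        with pytest.raises(ValueError, match="AGE"):
            si.build_design(incomplete_cohort, curve, "AGE")


class TestFitImputer:
    def test_lasso_at_zero_penalty_matches_glm(self, hgb_design):
        glm = si.fit_imputer(hgb_design, si.ImputerConfig(method="GLM", seed=1))
        lasso = si.fit_imputer(hgb_design, si.ImputerConfig(
            method="LASSO", seed=1, lasso_penalty_override=0.0))
        W = hgb_design.W
        assert np.allclose(glm.predict(W), lasso.predict(W), atol=1e-6)

    def test_exact_linear_truth_interpolated(self, hgb_design):
        design, y = linear_design(hgb_design)
        glm = si.fit_imputer(design, si.ImputerConfig(method="GLM", seed=2))
        assert np.allclose(glm.predict(design.W), y, atol=1e-10)

    def test_one_se_penalty_at_least_cv_minimum(self, hgb_design, fast_tuning):
        cfg = si.ImputerConfig(method="LASSO", seed=3, cv_folds=10)
        model = si.fit_imputer(hgb_design, cfg)
        assert model.tuning["penalty"] >= model.tuning["penalty_cv_min"]

    def test_too_few_observed_rows(self, hgb_design):
        from dataclasses import replace
        tiny = replace(hgb_design,
                       observed_rows=hgb_design.observed_rows[:5],
                       missing_rows=hgb_design.missing_rows)
        with pytest.raises(EstimationError, match="observed rows"):
            si.fit_imputer(tiny, si.ImputerConfig(method="GLM", seed=4))

    def test_constant_response_rejected(self, hgb_design):
        from dataclasses import replace
        flat = replace(hgb_design, y=np.ones(len(hgb_design.y)))
        with pytest.raises(EstimationError, match="HGB"):
            si.fit_imputer(flat, si.ImputerConfig(method="GLM", seed=5))


class TestImputeTarget:
    def test_noise_off_recovers_exact_linear_truth(self, hgb_design):
        design, y = linear_design(hgb_design)
        cfg = si.ImputerConfig(method="GLM", seed=6, noise=False)
        model = si.fit_imputer(design, cfg)
        vals = si.impute_target(model, design, cfg)
        assert np.allclose(vals, y[design.missing_rows], atol=1e-8)

    def test_noise_law_matches_observed_sd(self, cfg, calibrator, surv30):
        """Injected residual noise has variance sd(X_obs)^2."""
        spec = si.ScenarioSpec(n=4000, censor_target=0.30, miss_target=0.15, seed=31)
        coh = si.simulate_complete(spec, cfg.covariates, surv30, seed=31)
        mspec = calibrator.missingness_for(0.30, 0.15)
        inc = si.apply_missingness(coh, mspec, seed=32)
        frame = inc.to_frame()
        fit = si.fit_cox(frame, inc.complete_columns())
        curve = si.baseline_cumhaz(fit, frame, "KP")
        design = si.build_design(inc, curve, "HGB")
        icfg_off = si.ImputerConfig(method="GLM", seed=33, noise=False)
        model = si.fit_imputer(design, icfg_off)
        bare = si.impute_target(model, design, icfg_off)
        draws = []
        for s in range(40):
            icfg_on = si.ImputerConfig(method="GLM", seed=1000 + s, noise=True)
            draws.append(si.impute_target(model, design, icfg_on) - bare)
        resid = np.concatenate(draws)
        sd_obs = np.std(design.y[design.observed_rows], ddof=1)
        assert np.var(resid) == pytest.approx(sd_obs ** 2, rel=0.05)
        assert abs(np.mean(resid)) < 0.05 * sd_obs

    @pytest.mark.parametrize("method", si.METHODS)
    def test_binary_imputations_are_zero_one(self, incomplete_cohort, curve,
                                             method, fast_tuning):
        design = si.build_design(incomplete_cohort, curve, "PROG")
        cfg = si.ImputerConfig(method=method, seed=7, **fast_tuning)
        model = si.fit_imputer(design, cfg)
        vals = si.impute_target(model, design, cfg)
        assert set(np.unique(vals)) <= {0.0, 1.0}

    @pytest.mark.parametrize("method", si.METHODS)
    def test_continuous_imputations_finite(self, incomplete_cohort, curve,
                                           method, fast_tuning):
        design = si.build_design(incomplete_cohort, curve, "LALP")
        cfg = si.ImputerConfig(method=method, seed=8, **fast_tuning)
        model = si.fit_imputer(design, cfg)
        vals = si.impute_target(model, design, cfg)
        assert np.all(np.isfinite(vals))
        assert len(vals) == len(design.missing_rows)

    def test_no_missing_rows_is_noop(self, hgb_design):
        from dataclasses import replace
        design, y = linear_design(hgb_design)
        full = replace(design,
                       observed_rows=np.arange(len(y)),
                       missing_rows=np.arange(0))
        cfg = si.ImputerConfig(method="GLM", seed=9)
        model = si.fit_imputer(full, cfg)
        assert len(si.impute_target(model, full, cfg)) == 0


class TestImputeAll:
    @pytest.mark.parametrize("method", ["GLM", "LASSO", "MARS"])
    def test_completion_and_non_interference(self, incomplete_cohort, method,
                                             fast_tuning):
        cfg = si.ImputerConfig(method=method, seed=10, **fast_tuning)
        out = si.impute_all(incomplete_cohort, cfg)
        assert not out.X.isna().any().any()
        for t in incomplete_cohort.targets:
            keep = ~incomplete_cohort.mask[t].to_numpy(bool)
            assert np.allclose(out.X.loc[keep, t],
                               incomplete_cohort.X.loc[keep, t])
        assert out.method == method

    def test_deterministic_given_seed(self, incomplete_cohort, fast_tuning):
        cfg = si.ImputerConfig(method="LASSO", seed=11, **fast_tuning)
        a = si.impute_all(incomplete_cohort, cfg)
        b = si.impute_all(incomplete_cohort, cfg)
        assert a.X.equals(b.X)

    def test_iterated_hazard_refinement_runs(self, incomplete_cohort, fast_tuning):
        cfg = si.ImputerConfig(method="GLM", seed=12, h0_iterations=3, **fast_tuning)
        out = si.impute_all(incomplete_cohort, cfg)
        assert not out.X.isna().any().any()

    def test_tuning_log_recorded(self, incomplete_cohort, fast_tuning):
        cfg = si.ImputerConfig(method="LASSO", seed=13, **fast_tuning)
        out = si.impute_all(incomplete_cohort, cfg)
        assert set(out.tuning_log) == set(incomplete_cohort.targets)
        assert all("penalty" in v for v in out.tuning_log.values())


def test_child_seed_streams_distinct():
    seeds = {_child_seed(1, k) for k in range(100)}
    assert len(seeds) == 100
    assert all(0 <= s < 2 ** 31 for s in seeds)
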