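"""Impute one incomplete cohort with all five methods and refit the Cox model.

Each method fills PROG, HGB and LALP from the hazard-augmented design, then
the six-covariate analysis model is refit; the printed coefficients show how
much each method perturbs the estimates relative to the known truth.
Reduced tuning grids keep the run quick.
"""

import pandas as pd

import survimpute as si

cfg = si.default_config()
cal = si.Calibrator(cfg, calib_n=100_000)
surv = cal.survival_for(0.30)
mspec = cal.missingness_for(0.30, 0.15)

spec = si.ScenarioSpec(n=500, censor_target=0.30, miss_target=0.15, seed=20)
cohort = si.simulate_complete(spec, cfg.covariates, surv, seed=20)
incomplete = si.apply_missingness(cohort, mspec, seed=21)

rows = {"truth": cal.truth().beta}
for method in si.METHODS:
    icfg = si.ImputerConfig(method=method, seed=22, cv_folds=5,
                            svm_c_grid=[0.5, 2.0, 8.0],
                            svm_gamma_grid=[0.01, 0.05, 0.25],
                            rf_trees=100, rf_mtry_grid=[3, 6])
    imputed = si.impute_all(incomplete, icfg)
    fit = si.fit_cox(imputed.to_frame(), si.ANALYSIS_COVARIATES)
    rows[method] = fit.coef

print(pd.DataFrame(rows, index=si.ANALYSIS_COVARIATES).round(3).to_string())
# Rows are log-hazard coefficients.  Differences from the truth mix
# finite-sample Cox error with imputation error; single imputation with
# marginal-sd residual noise typically inflates the spread of the filled
# covariates slightly.
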