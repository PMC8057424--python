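"""Regression imputation of missing baseline covariates under five methods.

Every method fits the same cumulative-hazard-augmented imputation model: the
incomplete covariate is regressed on the fully observed baseline covariates
Z, the treatment arm, the event indicator delta, and the estimated baseline
cumulative hazard evaluated at the observed time,

    g(E[X_j | w_i]) = w_i' beta,   w_i = [z_i, arm_i, delta_i, H0(y_i)],

with g the identity for continuous targets and the logit for binary ones.
The five fitting engines are unpenalized GLM, LASSO (10-fold CV, one-SE
rule), additive MARS with GCV pruning, RBF-kernel SVM (10-fold CV grid
search), and random forest (mtry chosen by out-of-bag error).  Continuous
imputations receive a residual draw e ~ N(0, sd(X_obs)); binary imputations
are Bernoulli draws from the predicted probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVC, SVR

from .config import BINARY, ImputerConfig
from .mars import MarsRegressor
from .missingness import IncompleteCohort
from .survival import CumHazCurve, EstimationError, baseline_cumhaz, evaluate_cumhaz, fit_cox


def _child_seed(seed: int, *keys: int) -> int:
    """Derive an independent 31-bit child seed from (seed, keys)."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class ImputationDesign:
    """Predictor matrix and row partition for one incomplete covariate."""

    W: pd.DataFrame
    response_name: str
    y: np.ndarray                 # full-length response, NaN at missing rows
    observed_rows: np.ndarray
    missing_rows: np.ndarray
    kind: str                     # 'binary' or 'continuous'


@dataclass
class FittedImputer:
    """A fitted imputation regression: predicts E[X_j] (or P(X_j=1)) from W."""

    method: str
    kind: str
    predict: callable
    tuning: dict = field(default_factory=dict)


@dataclass
class ImputedCohort:
    """An incomplete cohort with every masked entry filled in."""

    X: pd.DataFrame
    T: np.ndarray
    Ctime: np.ndarray
    Y: np.ndarray
    delta: np.ndarray
    mask: pd.DataFrame
    truth_store: pd.DataFrame
    method: str = ""
    imputed_values: pd.DataFrame = field(default_factory=pd.DataFrame)
    tuning_log: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        df["T"] = self.T
        df["C"] = self.Ctime
        df["Y"] = self.Y
        df["delta"] = self.delta
        df["method"] = self.method
        return df


def build_design(cohort: IncompleteCohort, curve: CumHazCurve, target: str) -> ImputationDesign:
    """Assemble the 13-column predictor matrix for one incomplete covariate.

    W = [10 complete baseline covariates, ARM, delta, H0(Y)]; the other two
    incomplete covariates are excluded so W never contains missing entries.
    """
    if target not in cohort.targets:
        raise ValueError(f"{target!r} is not one of the incomplete covariates {cohort.targets}")
    W = cohort.X[cohort.complete_columns()].copy()
    W["delta"] = cohort.delta
    h = evaluate_cumhaz(curve, cohort.Y)
    # KP reaches -log(0) = inf when the largest observation is an event;
    # cap at the largest finite step so the design stays usable
    if np.isinf(h).any():
        finite = h[np.isfinite(h)]
        h = np.where(np.isinf(h), finite.max() if len(finite) else 0.0, h)
    W["cumhaz"] = h
    y = cohort.X[target].to_numpy(float)
    miss = cohort.mask[target].to_numpy(bool)
    idx = np.arange(cohort.n)
    kind = "binary" if target in BINARY else "continuous"
    return ImputationDesign(W=W, response_name=target, y=y,
                            observed_rows=idx[~miss], missing_rows=idx[miss],
                            kind=kind)


# ---------------------------------------------------------------------------
# method-specific fits

def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _fit_glm(X, y, kind):
    if kind == "continuous":
        m = LinearRegression().fit(X, y)
        return (lambda W: m.predict(np.asarray(W, float))), {}
    m = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
    return (lambda W: m.predict_proba(np.asarray(W, float))[:, 1]), {}


def _lasso_one_se_alpha(alphas, mean_err, se_err):
    """Largest penalty with CV error within one SE of the minimum."""
    i_min = int(np.argmin(mean_err))
    cutoff = mean_err[i_min] + se_err[i_min]
    ok = np.asarray(alphas)[mean_err <= cutoff]
    return float(ok.max()), float(np.asarray(alphas)[i_min])


def _alpha_grid(Xs, y, n_alphas):
    n = len(y)
    alpha_max = max(np.abs(Xs.T @ (y - y.mean())).max() / n, 1e-6)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-4), n_alphas)


def _fit_lasso(X, y, kind, cfg: ImputerConfig):
    Xs, mu, sd = _standardize(X)
    cv_seed = _child_seed(cfg.seed, 11)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cv_seed)
    alphas = _alpha_grid(Xs, y, cfg.lasso_n_alphas)

    if cfg.lasso_penalty_override is not None:
        alpha = max(float(cfg.lasso_penalty_override), 1e-12)
        chosen, a_min = alpha, alpha
    else:
        errs = np.empty((len(alphas), cfg.cv_folds))
        for f, (tr, te) in enumerate(kf.split(Xs)):
            for a_i, a in enumerate(alphas):
                if kind == "continuous":
                    m = Lasso(alpha=a, max_iter=50_000).fit(Xs[tr], y[tr])
                    pred = m.predict(Xs[te])
                    errs[a_i, f] = np.mean((y[te] - pred) ** 2)
                else:
                    m = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                           C=1.0 / (a * len(tr)), max_iter=5000)
                    m.fit(Xs[tr], y[tr])
                    p = np.clip(m.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
                    errs[a_i, f] = -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log1p(-p))
        mean_err = errs.mean(axis=1)
        se_err = errs.std(axis=1, ddof=1) / np.sqrt(cfg.cv_folds)
        chosen, a_min = _lasso_one_se_alpha(alphas, mean_err, se_err)

    if kind == "continuous":
        m = Lasso(alpha=chosen, max_iter=200_000, tol=1e-10).fit(Xs, y)
        predict = lambda W: m.predict((np.asarray(W, float) - mu) / sd)
    else:
        m = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                               C=1.0 / (chosen * len(y)), max_iter=5000).fit(Xs, y)
        predict = lambda W: m.predict_proba((np.asarray(W, float) - mu) / sd)[:, 1]
    return predict, {"penalty": chosen, "penalty_cv_min": a_min}


def _fit_mars(X, y, kind, cfg: ImputerConfig):
    m = MarsRegressor(max_terms=cfg.mars_max_terms).fit(X, y)
    if kind == "continuous":
        return m.predict, {"n_terms": len(m.terms_), "gcv": m.gcv_}
    predict = lambda W: np.clip(m.predict(W), 0.0, 1.0)
    return predict, {"n_terms": len(m.terms_), "gcv": m.gcv_}


def _fit_svm(X, y, kind, cfg: ImputerConfig):
    Xs, mu, sd = _standardize(X)
    cv_seed = _child_seed(cfg.seed, 12)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cv_seed)
    grid = {"C": list(cfg.svm_c_grid), "gamma": list(cfg.svm_gamma_grid)}
    if kind == "continuous":
        gs = GridSearchCV(SVR(kernel="rbf"), grid, cv=kf,
                          scoring="neg_mean_squared_error", n_jobs=1)
        gs.fit(Xs, y)
        best = gs.best_estimator_
        predict = lambda W: best.predict((np.asarray(W, float) - mu) / sd)
    else:
        # SVC's built-in Platt scaling; its deprecation notice is silenced
        # because the replacement wrapper changes the tuning-grid interface
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*probability.*",
                                    category=FutureWarning)
            gs = GridSearchCV(SVC(kernel="rbf", probability=True,
                                  random_state=_child_seed(cfg.seed, 13)),
                              grid, cv=kf, scoring="neg_log_loss", n_jobs=1)
            gs.fit(Xs, y)
        best = gs.best_estimator_

        def predict(W):
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*probability.*",
                                        category=FutureWarning)
                return best.predict_proba((np.asarray(W, float) - mu) / sd)[:, 1]
    return predict, {"C": gs.best_params_["C"], "gamma": gs.best_params_["gamma"]}


def _fit_rf(X, y, kind, cfg: ImputerConfig):
    p = X.shape[1]
    grid = sorted({min(m, p) for m in cfg.rf_mtry_grid})
    best = None
    for mtry in grid:
        seed = _child_seed(cfg.seed, 14, mtry)
        if kind == "continuous":
            m = RandomForestRegressor(n_estimators=cfg.rf_trees, max_features=mtry,
                                      oob_score=True, random_state=seed, n_jobs=1)
            m.fit(X, y)
            oob = float(np.mean((y - m.oob_prediction_) ** 2))
        else:
            m = RandomForestClassifier(n_estimators=cfg.rf_trees, max_features=mtry,
                                       oob_score=True, random_state=seed, n_jobs=1)
            m.fit(X, y)
            p1 = m.oob_decision_function_[:, list(m.classes_).index(1)]
            oob = float(np.mean((y - p1) ** 2))  # OOB Brier score
        if best is None or oob < best[0]:
            best = (oob, mtry, m)
    oob, mtry, m = best
    if kind == "continuous":
        predict = lambda W: m.predict(np.asarray(W, float))
    else:
        cls1 = list(m.classes_).index(1)
        predict = lambda W: m.predict_proba(np.asarray(W, float))[:, cls1]
    return predict, {"mtry": mtry, "oob_error": oob}


_FITTERS = {"GLM": _fit_glm, "LASSO": _fit_lasso, "MARS": _fit_mars,
            "SVM": _fit_svm, "RF": _fit_rf}


def fit_imputer(design: ImputationDesign, cfg: ImputerConfig) -> FittedImputer:
    """Fit the configured regression method on the observed rows of the design."""
    cfg.validate()
    obs = design.observed_rows
    if len(obs) < cfg.cv_folds:
        raise EstimationError(
            f"only {len(obs)} observed rows for {design.response_name}; "
            f"need at least cv_folds={cfg.cv_folds}")
    X = design.W.to_numpy(float)[obs]
    y = design.y[obs]
    if np.ptp(y) == 0:
        raise EstimationError(f"response {design.response_name!r} is constant on observed rows")
    fitter = _FITTERS[cfg.method]
    if cfg.method == "GLM":
        predict, tuning = fitter(X, y, design.kind)
    else:
        predict, tuning = fitter(X, y, design.kind, cfg)
    return FittedImputer(method=cfg.method, kind=design.kind,
                         predict=predict, tuning=tuning)


def impute_target(model: FittedImputer, design: ImputationDesign,
                  cfg: ImputerConfig) -> np.ndarray:
    """Imputed values for the missing rows of one target.

    Continuous: prediction plus N(0, sd(X_obs)) residual noise (bare
    prediction when noise is off).  Binary: Bernoulli draw from the
    predicted event probability.
    """
    miss = design.missing_rows
    if len(miss) == 0:
        return np.empty(0)
    pred = np.asarray(model.predict(design.W.iloc[miss]), dtype=float)
    rng = np.random.default_rng(_child_seed(cfg.seed, 21, len(miss)))
    if design.kind == "binary":
        p = np.clip(pred, 0.0, 1.0)
        return (rng.uniform(size=len(miss)) < p).astype(float)
    if cfg.noise:
        sd = float(np.std(design.y[design.observed_rows], ddof=1))
        pred = pred + rng.normal(0.0, sd, size=len(miss))
    return pred


def impute_all(cohort: IncompleteCohort, cfg: ImputerConfig,
               curve: CumHazCurve | None = None) -> ImputedCohort:
    """Impute all three incomplete covariates under one method.

    The baseline cumulative hazard is first estimated from a Cox fit on the
    complete covariates only (Kalbfleisch-Prentice form); each target is then
    imputed independently from its own design.  With ``h0_iterations > 1``
    the hazard is re-estimated on the imputed data (all covariates) and the
    targets re-imputed, stopping early when the hazard curve changes by less
    than ``h0_tol`` in relative sup-norm at the event times.
    """
    cfg.validate()
    frame = cohort.to_frame()
    complete_covs = cohort.complete_columns()
    if curve is None:
        fit0 = fit_cox(frame, complete_covs)
        curve = baseline_cumhaz(fit0, frame, "KP")

    X = cohort.X.copy()
    tuning_log: dict = {}
    imputed_vals: dict = {}
    for it in range(max(1, cfg.h0_iterations)):
        work = IncompleteCohort(X=cohort.X, T=cohort.T, Ctime=cohort.Ctime,
                                Y=cohort.Y, delta=cohort.delta,
                                mask=cohort.mask, truth_store=cohort.truth_store)
        for t_i, target in enumerate(cohort.targets):
            design = build_design(work, curve, target)
            target_cfg = ImputerConfig(**{**cfg.__dict__,
                                          "seed": _child_seed(cfg.seed, 31, it, t_i)})
            model = fit_imputer(design, target_cfg)
            vals = impute_target(model, design, target_cfg)
            col = X[target].copy()
            col.iloc[design.missing_rows] = vals
            X[target] = col
            tuning_log[target] = model.tuning
            imputed_vals[target] = pd.Series(vals, index=X.index[design.missing_rows])
        if it + 1 >= max(1, cfg.h0_iterations):
            break
        # re-estimate the hazard on the now-complete data
        filled = frame.copy()
        for t in cohort.targets:
            filled[t] = X[t]
        fit_it = fit_cox(filled, complete_covs + list(cohort.targets))
        new_curve = baseline_cumhaz(fit_it, filled, "KP")
        ref = np.maximum(np.abs(evaluate_cumhaz(curve, new_curve.times)), 1e-12)
        rel_change = float(np.max(np.abs(new_curve.H - evaluate_cumhaz(curve, new_curve.times)) / ref))
        curve = new_curve
        if rel_change < cfg.h0_tol:
            break

    assert not X[cohort.targets].isna().any().any()
    return ImputedCohort(X=X, T=cohort.T.copy(), Ctime=cohort.Ctime.copy(),
                         Y=cohort.Y.copy(), delta=cohort.delta.copy(),
                         mask=cohort.mask.copy(), truth_store=cohort.truth_store.copy(),
                         method=cfg.method,
                         imputed_values=pd.DataFrame(imputed_vals),
                         tuning_log=tuning_log)
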