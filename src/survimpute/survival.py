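"""Cox proportional-hazards fitting and baseline cumulative-hazard estimation.

The partial-likelihood fit is delegated to lifelines (Efron tie handling;
irrelevant on tie-free simulated data but defined for user data).  Baseline
cumulative hazards are computed at the all-zero covariate reference, without
centering, by either the Kalbfleisch-Prentice product-form estimator or the
Nelson-Aalen/Breslow increment estimator.  Under the null model (no
covariates) KP reduces exactly to -log of the Kaplan-Meier survival curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import optimize, stats

Z975 = float(stats.norm.ppf(0.975))


class EstimationError(RuntimeError):
    """Model estimation failed (no events, non-convergence, ...)."""


@dataclass
class CoxFit:
    """Cox partial-likelihood estimates with Wald 95% intervals."""

    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    covariate_names: list[str]


@dataclass
class CumHazCurve:
    """Right-continuous step estimate of the baseline cumulative hazard."""

    times: np.ndarray
    H: np.ndarray
    estimator_tag: str

    def __call__(self, t) -> np.ndarray:
        return evaluate_cumhaz(self, t)


def fit_cox(cohort: pd.DataFrame, covariates: list[str],
            duration_col: str = "Y", event_col: str = "delta") -> CoxFit:
    """Fit the Cox model of observed time on the requested covariates.

    ECOG enters as a single numeric 0/1/2 column, so the six-covariate
    analysis model returns exactly six coefficients.  Requires at least one
    event and no missing entries among the requested columns.
    """
    if cohort[event_col].sum() == 0:
        raise EstimationError("no events in cohort; Cox model is undefined")
    cols = list(covariates) + [duration_col, event_col]
    df = cohort[cols]
    if df[covariates].isna().any().any():
        raise EstimationError("missing entries among requested covariates")
    if not covariates:
        return CoxFit(coef=np.array([]), se=np.array([]), ci_low=np.array([]),
                      ci_high=np.array([]), loglik=0.0, covariate_names=[])
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise EstimationError(f"Cox fit did not converge: {err}") from err
    coef = cph.params_.reindex(covariates).to_numpy(float)
    se = cph.standard_errors_.reindex(covariates).to_numpy(float)
    return CoxFit(coef=coef, se=se,
                  ci_low=coef - Z975 * se, ci_high=coef + Z975 * se,
                  loglik=float(cph.log_likelihood_),
                  covariate_names=list(covariates))


def _risk_scores(fit: CoxFit, cohort: pd.DataFrame) -> np.ndarray:
    if not fit.covariate_names:
        return np.ones(len(cohort))
    Xb = cohort[fit.covariate_names].to_numpy(float) @ fit.coef
    return np.exp(Xb)


def _kp_survival_factor(risk_event: np.ndarray, risk_total: float) -> float:
    """Conditional survival factor at one event time.

    Solves sum_{j in D} e_j / (1 - pi^{e_j}) = risk_total for pi in (0, 1);
    with a single event the closed form is (1 - e/r)^{1/e}.
    """
    if len(risk_event) == 1:
        e = float(risk_event[0])
        inner = 1.0 - e / risk_total
        if inner <= 0:
            return 0.0
        return inner ** (1.0 / e)

    def f(pi: float) -> float:
        return float(np.sum(risk_event / (1.0 - pi ** risk_event)) - risk_total)

    lo, hi = 1e-12, 1.0 - 1e-12
    if f(hi) < 0:  # heavy ties: mass exhausts the risk set
        return 0.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def baseline_cumhaz(fit: CoxFit, cohort: pd.DataFrame, estimator: str = "KP",
                    duration_col: str = "Y", event_col: str = "delta") -> CumHazCurve:
    """Baseline cumulative hazard at the all-zero covariate reference.

    ``estimator='KP'`` uses the Kalbfleisch-Prentice product-form
    conditional-survival estimator, H = -log prod pi_i; ``estimator='NA'``
    the Nelson-Aalen/Breslow increments d_i / sum_{risk} exp(x'beta).
    """
    if estimator not in ("KP", "NA"):
        raise ValueError(f"unknown estimator tag {estimator!r}; expected 'KP' or 'NA'")
    y = cohort[duration_col].to_numpy(float)
    d = cohort[event_col].to_numpy(int)
    r = _risk_scores(fit, cohort)
    order = np.argsort(y, kind="stable")
    y, d, r = y[order], d[order], r[order]
    # cumulative risk mass from each index onward = risk set at time y[i]
    risk_tail = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
    event_times = np.unique(y[d == 1])
    H = np.empty(len(event_times))
    acc = 0.0
    log_surv = 0.0
    for i, t in enumerate(event_times):
        at_risk_idx = np.searchsorted(y, t, side="left")
        risk_total = risk_tail[at_risk_idx]
        in_event = (y == t) & (d == 1)
        if estimator == "NA":
            acc += in_event.sum() / risk_total
            H[i] = acc
        else:
            pi = _kp_survival_factor(r[in_event], risk_total)
            if pi <= 0:
                log_surv = -np.inf
            else:
                log_surv += np.log(pi)
            H[i] = -log_surv
    return CumHazCurve(times=event_times, H=H, estimator_tag=estimator)


def evaluate_cumhaz(curve: CumHazCurve, times) -> np.ndarray:
    """Right-continuous step lookup: H(t) includes the increment at t itself."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if (t < 0).any():
        raise ValueError("times must be nonnegative")
    idx = np.searchsorted(curve.times, t, side="right")
    padded = np.concatenate([[0.0], curve.H])
    return padded[idx]
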