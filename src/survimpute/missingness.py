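"""Missing-at-random masking of the three designated covariates.

For each target (PROG, HGB, LALP) a logistic model maps the fully observed
baseline covariates plus ARM to a per-subject missingness probability; a
Bernoulli draw at that probability blanks the entry.  Because the
probabilities depend only on always-complete variables, the mechanism is
MAR by construction.  Intercepts are calibrated by bisection so the mean
missingness probability over a cohort hits the target rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import MISSING_TARGETS, MissingnessSpec
from .cohort import CompleteCohort


class SchemaError(KeyError):
    """A required column is absent from the cohort table."""


@dataclass
class IncompleteCohort:
    """A cohort with MAR gaps in the three target covariates.

    ``X`` contains NaN where entries were blanked; ``mask`` is an n x 3
    indicator frame (1 = missing) over the target columns and ``truth_store``
    retains the pre-deletion values so oracle scoring and exact restoration
    remain possible.
    """

    X: pd.DataFrame
    T: np.ndarray
    Ctime: np.ndarray
    Y: np.ndarray
    delta: np.ndarray
    mask: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth_store: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def targets(self) -> list[str]:
        return list(self.mask.columns)

    def complete_columns(self) -> list[str]:
        return [c for c in self.X.columns if c not in self.mask.columns]

    def restore(self) -> CompleteCohort:
        """Undo the masking bit-exactly using the stored true values."""
        X = self.X.copy()
        for t in self.mask.columns:
            miss = self.mask[t].to_numpy(bool)
            X.loc[miss, t] = self.truth_store.loc[miss, t]
            X[t] = X[t].astype(self.truth_store[t].dtype)
        return CompleteCohort(X=X, T=self.T.copy(), Ctime=self.Ctime.copy(),
                              Y=self.Y.copy(), delta=self.delta.copy())

    def to_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        df["T"] = self.T
        df["C"] = self.Ctime
        df["Y"] = self.Y
        df["delta"] = self.delta
        return df

    def write_tables(self, cohort_path, mask_path) -> None:
        # Blanked entries serialize as empty fields; the mask table is the audit copy.
        self.to_frame().to_csv(cohort_path, index=False)
        self.mask.astype(int).to_csv(mask_path, index_label="subject")


def _mar_predictors(cohort: CompleteCohort, slopes: dict[str, float]) -> np.ndarray:
    lp = np.zeros(cohort.n)
    for name, b in slopes.items():
        if name in ("Y", "T", "C", "delta"):
            raise SchemaError(f"missingness model may not use outcome column {name!r}")
        if name not in cohort.X.columns:
            raise SchemaError(f"missingness predictor {name!r} absent from cohort")
        lp += b * cohort.X[name].to_numpy(float)
    return lp


def missingness_probabilities(cohort: CompleteCohort, spec: MissingnessSpec) -> pd.DataFrame:
    """Per-subject, per-target missingness probabilities (deterministic in the covariates)."""
    spec.validate()
    out = {}
    for t in spec.targets:
        lp = _mar_predictors(cohort, spec.slopes.get(t, {}))
        if spec.miss_target == 0:
            out[t] = np.zeros(cohort.n)
        else:
            out[t] = expit(spec.intercepts[t] + lp)
    return pd.DataFrame(out, index=cohort.X.index)


def calibrate_intercept(slopes: dict[str, float], cohort: CompleteCohort,
                        miss_target: float, tol: float = 1e-4) -> float:
    """Intercept alpha with mean expit(alpha + slopes.z) = miss_target.

    The mean probability is strictly increasing in alpha and spans (0, 1),
    so bisection always converges; with all-zero slopes the closed form is
    logit(miss_target).
    """
    if not 0 < miss_target < 1:
        raise ValueError("miss_target must lie in (0, 1)")
    lp = _mar_predictors(cohort, slopes)
    if np.allclose(lp, 0.0):
        return float(logit(miss_target))

    def mean_prob(a: float) -> float:
        return float(np.mean(expit(a + lp)))

    lo, hi = -50.0, 50.0
    while mean_prob(lo) > miss_target:
        lo *= 2.0
    while mean_prob(hi) < miss_target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = mean_prob(mid)
        if abs(f - miss_target) <= tol:
            return mid
        if f < miss_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_missingness(spec: MissingnessSpec, cohort: CompleteCohort,
                          miss_target: float) -> MissingnessSpec:
    """Return a copy of ``spec`` with intercepts calibrated on ``cohort``."""
    if miss_target == 0:
        return replace(spec, intercepts={t: -np.inf for t in spec.targets},
                       miss_target=0.0)
    intercepts = {t: calibrate_intercept(spec.slopes.get(t, {}), cohort, miss_target)
                  for t in spec.targets}
    return replace(spec, intercepts=intercepts, miss_target=miss_target)


def apply_missingness(cohort: CompleteCohort, spec: MissingnessSpec,
                      seed: int | np.random.Generator) -> IncompleteCohort:
    """Blank entries of the three targets by independent Bernoulli draws.

    Masked values are retained in ``truth_store`` and replaced with NaN in
    the working matrix; unmasked entries are untouched.
    """
    spec.validate()
    for t in spec.targets:
        if t not in cohort.X.columns:
            raise SchemaError(f"target column {t!r} absent from cohort")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probs = missingness_probabilities(cohort, spec)
    mask = pd.DataFrame({t: rng.uniform(size=cohort.n) < probs[t].to_numpy()
                         for t in spec.targets}, index=cohort.X.index)
    X = cohort.X.copy()
    truth = cohort.X[spec.targets].copy()
    for t in spec.targets:
        X[t] = X[t].astype(float)
        X.loc[mask[t].to_numpy(), t] = np.nan
    return IncompleteCohort(X=X, T=cohort.T.copy(), Ctime=cohort.Ctime.copy(),
                            Y=cohort.Y.copy(), delta=cohort.delta.copy(),
                            mask=mask, truth_store=truth)
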