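"""Configuration objects for the simulation benchmark.

The cohort emulated here is a two-arm oncology trial in advanced prostate
cancer: 13 baseline covariates (7 continuous, 5 binary, 1 three-level
performance-status score) plus a balanced binary treatment arm, a Weibull
time-to-death outcome under proportional hazards, independent Weibull
censoring, and missing-at-random gaps in three of the covariates.

All knobs live in plain dataclasses that round-trip through YAML, so a run
is fully described by one structured text file plus a root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

# Baseline covariate roster (treatment arm ARM is handled separately: it is
# a balanced design factor, not a draw from the latent Gaussian).
CONTINUOUS = ["AGE", "HGB", "LALP", "LPSA", "TIME_HORMONE", "YRSINCEDIAG", "BMI"]
BINARY = ["PROG", "PAIN", "WHITE", "CHEMO", "MEAS_DIS"]
THREE_LEVEL = ["ECOG"]
COVARIATES = ["ECOG", "PROG", "PAIN", "WHITE", "CHEMO", "MEAS_DIS",
              "AGE", "HGB", "LALP", "LPSA", "TIME_HORMONE", "YRSINCEDIAG", "BMI"]

#: Covariates of the final analysis model (six Cox coefficients).
ANALYSIS_COVARIATES = ["PROG", "HGB", "LALP", "ARM", "ECOG", "AGE"]

#: The three covariates subjected to missingness.
MISSING_TARGETS = ["PROG", "HGB", "LALP"]

#: The five imputation methods under comparison.
METHODS = ["GLM", "LASSO", "MARS", "SVM", "RF"]


class ConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


class CalibrationError(RuntimeError):
    """Raised when a calibration target cannot be reached."""


def _as_builtin(obj):
    """Recursively convert numpy containers to plain Python for YAML."""
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _as_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_builtin(v) for v in obj]
    return obj


@dataclass
class CovariateModel:
    """Latent-Gaussian model for the 13 correlated mixed-type covariates.

    Continuous margins are affine transforms of the latent standard normals;
    categorical margins are obtained by inverse-transform sampling, i.e.
    thresholding the latent margin at standard-normal quantiles of the
    configured category probabilities.
    """

    names: list[str] = field(default_factory=lambda: list(COVARIATES))
    kinds: dict[str, str] = field(default_factory=dict)
    latent_corr: np.ndarray | None = None
    cont_means: dict[str, float] = field(default_factory=dict)
    cont_sds: dict[str, float] = field(default_factory=dict)
    cat_probs: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kinds:
            self.kinds = {**{c: "continuous" for c in CONTINUOUS},
                          **{c: "binary" for c in BINARY},
                          **{c: "three-level" for c in THREE_LEVEL}}
        if self.latent_corr is not None:
            self.latent_corr = np.asarray(self.latent_corr, dtype=float)

    def validate(self) -> None:
        p = len(self.names)
        R = self.latent_corr
        if R is None or R.shape != (p, p):
            raise ConfigError(f"latent_corr must be {p}x{p}")
        if not np.allclose(R, R.T):
            raise CalibrationError("latent_corr is not symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise CalibrationError("latent_corr diagonal must be 1")
        eigmin = np.linalg.eigvalsh(R).min()
        if eigmin <= 0:
            raise CalibrationError(
                f"latent_corr is not positive definite (min eigenvalue {eigmin:.3g})")
        for name in self.names:
            kind = self.kinds[name]
            if kind == "continuous":
                if self.cont_sds[name] <= 0:
                    raise ConfigError(f"cont_sds[{name}] must be positive")
            else:
                probs = np.asarray(self.cat_probs[name], dtype=float)
                want = 2 if kind == "binary" else 3
                if len(probs) != want:
                    raise ConfigError(f"cat_probs[{name}] needs {want} entries")
                if abs(probs.sum() - 1.0) > 1e-12:
                    raise ConfigError(f"cat_probs[{name}] must sum to 1")

    def to_dict(self) -> dict:
        return _as_builtin(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateModel":
        return cls(**d)


@dataclass
class SurvivalModel:
    """Weibull proportional-hazards outcome model plus independent censoring.

    Failure times follow h(t|x) = h0(t) exp(x'beta) with Weibull baseline of
    shape ``weibull_shape`` and scale ``baseline_scale``.  ``beta`` holds the
    true log-hazard coefficients of the six analysis covariates; the ARM
    entry and ``baseline_scale`` are calibrated so the two arms attain the
    configured median survival times.  Censoring is an independent Weibull
    with ``censor_shape``/``censor_scale``, the scale calibrated to a target
    censoring fraction.
    """

    weibull_shape: float = 1.2
    baseline_scale: float | None = None
    beta: dict[str, float] = field(default_factory=lambda: {
        "PROG": 0.40, "HGB": -0.15, "LALP": 0.35,
        "ARM": None, "ECOG": 0.45, "AGE": 0.01})
    median_experimental: float = 15.0
    median_control: float = 11.0
    censor_shape: float = 1.2
    censor_scale: float | None = None

    def validate(self, *, require_calibrated: bool = False) -> None:
        if self.weibull_shape <= 0 or self.censor_shape <= 0:
            raise ConfigError("Weibull shapes must be positive")
        if self.median_experimental <= 0 or self.median_control <= 0:
            raise ConfigError("median targets must be positive")
        if require_calibrated:
            if self.baseline_scale is None or self.baseline_scale <= 0:
                raise ConfigError("baseline_scale is not calibrated")
            if self.beta.get("ARM") is None:
                raise ConfigError("ARM coefficient is not calibrated")

    def to_dict(self) -> dict:
        return _as_builtin(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalModel":
        return cls(**d)


@dataclass
class ScenarioSpec:
    """One cell of the simulation grid: sample size x censoring x missingness."""

    n: int
    censor_target: float
    miss_target: float
    reps: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not 0 < self.censor_target < 1:
            raise ConfigError("censor_target must lie in (0, 1)")
        if not 0 <= self.miss_target < 1:
            raise ConfigError("miss_target must lie in [0, 1)")
        if self.reps < 1:
            raise ConfigError("reps must be >= 1")

    def label(self) -> str:
        return f"N{self.n}_C{int(round(self.censor_target * 100))}_M{int(round(self.miss_target * 100))}"


@dataclass
class MissingnessSpec:
    """Calibrated logistic missing-at-random mechanism for the three targets.

    For each target the probability of missingness is
    inverse-logit(intercept + slopes . z) where z runs over the complete
    baseline covariates and ARM only; the outcome never enters, which keeps
    the mechanism in the MAR class by construction.
    """

    targets: list[str] = field(default_factory=lambda: list(MISSING_TARGETS))
    slopes: dict[str, dict[str, float]] = field(default_factory=dict)
    intercepts: dict[str, float] = field(default_factory=dict)
    miss_target: float = 0.0

    def validate(self) -> None:
        if sorted(self.targets) != sorted(MISSING_TARGETS):
            raise ConfigError(f"targets must be exactly {MISSING_TARGETS}")
        if not 0 <= self.miss_target < 1:
            raise ConfigError("miss_target must lie in [0, 1)")

    def to_dict(self) -> dict:
        return _as_builtin(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "MissingnessSpec":
        return cls(**d)


@dataclass
class ImputerConfig:
    """Per-method tuning rules for the imputation regressions.

    LASSO penalties come from 10-fold cross-validation with the
    one-standard-error rule; SVM regularization/kernel coefficient from a
    10-fold CV grid search on a log2 lattice; RF candidate-split counts
    (mtry) from out-of-bag error; MARS prunes by generalized
    cross-validation.  ``noise`` adds the residual draw e ~ N(0, sd(X_obs))
    to continuous imputations (binary targets are Bernoulli draws from the
    predicted probability instead).
    """

    method: str = "GLM"
    cv_folds: int = 10
    lasso_rule: str = "one-SE"
    lasso_n_alphas: int = 50
    lasso_penalty_override: float | None = None
    svm_c_grid: list[float] = field(
        default_factory=lambda: [2.0 ** k for k in range(-3, 8)])
    svm_gamma_grid: list[float] = field(
        default_factory=lambda: [2.0 ** k for k in range(-7, 4)])
    rf_trees: int = 500
    rf_mtry_grid: list[int] = field(default_factory=lambda: [2, 3, 4, 6])
    mars_max_terms: int = 15
    h0_iterations: int = 1
    h0_tol: float = 1e-4
    noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if not self.svm_c_grid or not self.svm_gamma_grid or not self.rf_mtry_grid:
            raise ConfigError("tuning grids must be nonempty")
        if self.lasso_rule != "one-SE":
            raise ConfigError("only the one-SE LASSO rule is supported")


@dataclass
class GridConfig:
    """Full simulation grid: levels, methods, replicate count, seed, output."""

    n_levels: list[int] = field(default_factory=lambda: [200, 500, 1000])
    c_levels: list[float] = field(default_factory=lambda: [0.10, 0.30])
    m_levels: list[float] = field(default_factory=lambda: [0.05, 0.10, 0.15])
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    reps: int = 200
    root_seed: int = 20200904
    out_dir: str = "results"

    def validate(self) -> None:
        if not (self.n_levels and self.c_levels and self.m_levels):
            raise ConfigError("level sets must be nonempty")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ConfigError(f"unknown methods: {bad}")
        if self.reps < 1:
            raise ConfigError("reps must be >= 1")


@dataclass
class BenchmarkConfig:
    """Top-level bundle serialized to/from one YAML file."""

    covariates: CovariateModel
    survival: SurvivalModel
    missingness: MissingnessSpec
    grid: GridConfig
    imputer_defaults: ImputerConfig = field(default_factory=ImputerConfig)

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates.to_dict(),
            "survival": self.survival.to_dict(),
            "missingness": self.missingness.to_dict(),
            "grid": _as_builtin(asdict(self.grid)),
            "imputer_defaults": _as_builtin(asdict(self.imputer_defaults)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        return cls(
            covariates=CovariateModel.from_dict(d["covariates"]),
            survival=SurvivalModel.from_dict(d["survival"]),
            missingness=MissingnessSpec.from_dict(d["missingness"]),
            grid=GridConfig(**d["grid"]),
            imputer_defaults=ImputerConfig(**d.get("imputer_defaults", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "BenchmarkConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def exchangeable_corr(p: int, rho: float = 0.2) -> np.ndarray:
    """Exchangeable correlation matrix with off-diagonal ``rho``."""
    R = np.full((p, p), rho)
    np.fill_diagonal(R, 1.0)
    return R


def default_covariate_model(rho: float = 0.2) -> CovariateModel:
    """Clinically plausible defaults for an advanced prostate-cancer trial.

    Marginal moments and category probabilities are chosen to be realistic
    for the named covariates (age in years, hemoglobin in g/dL, log alkaline
    phosphatase and log PSA, months on hormone therapy, years since
    diagnosis, BMI in kg/m^2); the latent correlation is exchangeable with
    rho = 0.2 to induce moderate dependence among all covariates.
    """
    model = CovariateModel(
        latent_corr=exchangeable_corr(len(COVARIATES), rho),
        cont_means={"AGE": 68.0, "HGB": 12.5, "LALP": 4.8, "LPSA": 4.0,
                    "TIME_HORMONE": 30.0, "YRSINCEDIAG": 6.0, "BMI": 28.0},
        cont_sds={"AGE": 8.0, "HGB": 1.8, "LALP": 0.8, "LPSA": 1.5,
                  "TIME_HORMONE": 18.0, "YRSINCEDIAG": 4.0, "BMI": 4.5},
        cat_probs={"PROG": [0.4, 0.6], "PAIN": [0.55, 0.45],
                   "WHITE": [0.15, 0.85], "CHEMO": [0.7, 0.3],
                   "MEAS_DIS": [0.45, 0.55], "ECOG": [0.35, 0.55, 0.10]},
    )
    model.validate()
    return model


def default_missingness_slopes() -> dict[str, dict[str, float]]:
    """Moderate MAR dependence on performance status, age and disease burden.

    Slopes are on standardized scales for continuous predictors (AGE per
    year: 0.02 ~ 0.16 per SD).  Intercepts are calibrated per target and
    scenario, so only relative dependence matters here.
    """
    dep = {"ECOG": 0.30, "AGE": 0.02, "MEAS_DIS": 0.30}
    return {t: dict(dep) for t in MISSING_TARGETS}


def default_config() -> BenchmarkConfig:
    return BenchmarkConfig(
        covariates=default_covariate_model(),
        survival=SurvivalModel(),
        missingness=MissingnessSpec(slopes=default_missingness_slopes()),
        grid=GridConfig(),
    )
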