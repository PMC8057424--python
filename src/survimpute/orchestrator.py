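"""Scenario-grid execution: calibration, replication, aggregation, output.

The full study is a 3 x 2 x 3 grid (sample size x censoring x missingness)
of scenarios, each run for a configured number of replicates.  A replicate
simulates a fresh complete cohort, imposes MAR missingness, imputes with
each requested method, refits the six-covariate Cox analysis model, and
stores the coefficient estimates.  Replicate seeds are derived from the
root seed by a counter-based scheme (root_seed, scenario index, replicate
index), so replicates are individually reproducible and order-independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (ANALYSIS_COVARIATES, BenchmarkConfig, ConfigError,
                     GridConfig, ImputerConfig, ScenarioSpec)
from .cohort import calibrate_censoring_scale, calibrate_survival_model, simulate_complete
from .evaluation import (RepResults, TrueParams, good_counts, rank_methods,
                         summaries_frame, summarize)
from .imputers import impute_all
from .missingness import apply_missingness, calibrate_missingness
from .survival import EstimationError, baseline_cumhaz, fit_cox

log = logging.getLogger("survimpute")


@dataclass
class RunManifest:
    """Record of seeds, calibrations and outputs that produced a run."""

    config_hash: str
    root_seed: int
    calibrations: dict = field(default_factory=dict)
    scenarios: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def config_hash(cfg: BenchmarkConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def enumerate_scenarios(grid: GridConfig) -> list[ScenarioSpec]:
    """Cartesian product n_levels x c_levels x m_levels, in that nesting order."""
    grid.validate()
    return [ScenarioSpec(n=n, censor_target=c, miss_target=m, reps=grid.reps)
            for n in grid.n_levels for c in grid.c_levels for m in grid.m_levels]


def _replicate_seed(root_seed: int, scenario_idx: int, rep: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(root_seed), int(scenario_idx), int(rep), int(stream)])
    return np.random.default_rng(ss)


def _replicate_int_seed(root_seed: int, scenario_idx: int, rep: int, stream: int) -> int:
    ss = np.random.SeedSequence([int(root_seed), int(scenario_idx), int(rep), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


class Calibrator:
    """Computes and caches per-(C, M) calibration artifacts."""

    def __init__(self, cfg: BenchmarkConfig, calib_n: int = 100_000,
                 calib_seed: int = 424242):
        self.cfg = cfg
        self.calib_n = calib_n
        self.calib_seed = calib_seed
        self.survival = calibrate_survival_model(
            cfg.covariates, cfg.survival, calib_n=max(calib_n, 100_000),
            seed=calib_seed)
        self._censor: dict[float, float] = {}
        self._missing: dict[tuple[float, float], object] = {}

    def survival_for(self, censor_target: float):
        from dataclasses import replace
        if censor_target not in self._censor:
            self._censor[censor_target] = calibrate_censoring_scale(
                self.survival, self.cfg.covariates, censor_target,
                calib_n=self.calib_n, seed=self.calib_seed + 1)
        return replace(self.survival, censor_scale=self._censor[censor_target])

    def missingness_for(self, censor_target: float, miss_target: float):
        key = (censor_target, miss_target)
        if key not in self._missing:
            surv = self.survival_for(censor_target)
            spec = ScenarioSpec(n=self.calib_n, censor_target=censor_target,
                                miss_target=miss_target, seed=self.calib_seed + 2)
            cohort = simulate_complete(spec, self.cfg.covariates, surv,
                                       seed=self.calib_seed + 2)
            self._missing[key] = calibrate_missingness(
                self.cfg.missingness, cohort, miss_target)
        return self._missing[key]

    def truth(self) -> TrueParams:
        beta = np.array([self.survival.beta[c] for c in ANALYSIS_COVARIATES])
        return TrueParams(beta=beta, names=list(ANALYSIS_COVARIATES))

    def summary(self) -> dict:
        return {"baseline_scale": self.survival.baseline_scale,
                "beta": self.survival.beta,
                "censor_scales": dict(self._censor),
                "missingness_intercepts": {
                    f"C{c}_M{m}": spec.intercepts
                    for (c, m), spec in self._missing.items()}}


def run_scenario(scenario: ScenarioSpec, methods: list[str], cfg: BenchmarkConfig,
                 calibrator: Calibrator, scenario_idx: int = 0,
                 root_seed: int | None = None) -> dict[str, RepResults]:
    """Run all replicates of one scenario and collect per-method Cox estimates.

    Replicate-level failures (non-convergent fits and the like) are logged
    with their seed and skipped; the skip count is reported on the result.
    """
    scenario.validate()
    if root_seed is None:
        root_seed = cfg.grid.root_seed
    surv = calibrator.survival_for(scenario.censor_target)
    miss_spec = calibrator.missingness_for(scenario.censor_target, scenario.miss_target)
    store = {m: {"coef": [], "se": [], "lo": [], "hi": [], "skipped": 0}
             for m in methods}
    for rep in range(scenario.reps):
        cohort = simulate_complete(scenario, cfg.covariates, surv,
                                   seed=_replicate_seed(root_seed, scenario_idx, rep, 0))
        incomplete = apply_missingness(cohort, miss_spec,
                                       seed=_replicate_seed(root_seed, scenario_idx, rep, 1))
        # the hazard-augmented design's curve depends only on the complete
        # covariates, so it is shared across methods
        frame = incomplete.to_frame()
        try:
            fit0 = fit_cox(frame, incomplete.complete_columns())
            curve = baseline_cumhaz(fit0, frame, "KP")
        except EstimationError as err:
            log.warning("replicate %d of %s skipped for all methods: %s",
                        rep, scenario.label(), err)
            for m in methods:
                store[m]["skipped"] += 1
            continue
        for m_i, method in enumerate(methods):
            icfg = ImputerConfig(**{**cfg.imputer_defaults.__dict__,
                                    "method": method,
                                    "seed": _replicate_int_seed(root_seed, scenario_idx,
                                                                rep, 100 + m_i)})
            try:
                imputed = impute_all(incomplete, icfg, curve=curve)
                fit = fit_cox(imputed.to_frame(), ANALYSIS_COVARIATES)
            except EstimationError as err:
                log.warning("replicate %d (%s, %s) skipped: %s",
                            rep, scenario.label(), method, err)
                store[method]["skipped"] += 1
                continue
            store[method]["coef"].append(fit.coef)
            store[method]["se"].append(fit.se)
            store[method]["lo"].append(fit.ci_low)
            store[method]["hi"].append(fit.ci_high)
    out = {}
    for method in methods:
        s = store[method]
        if not s["coef"]:
            raise EstimationError(f"no replicate of {scenario.label()} succeeded for {method}")
        out[method] = RepResults(coef=np.array(s["coef"]), se=np.array(s["se"]),
                                 ci_low=np.array(s["lo"]), ci_high=np.array(s["hi"]),
                                 names=list(ANALYSIS_COVARIATES),
                                 n_skipped=s["skipped"])
    return out


def summarize_and_rank(all_results: dict[tuple, dict[str, RepResults]],
                       truth: TrueParams,
                       grid: GridConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the five statistics per scenario/method, then rank per (N, C) block."""
    expected = {(n, c, m) for n in grid.n_levels for c in grid.c_levels
                for m in grid.m_levels}
    missing = expected - set(all_results)
    if missing:
        raise ValueError(f"missing scenario cells: {sorted(missing)}")
    records = []
    for (n, c, m), per_method in sorted(all_results.items()):
        for method, reps in per_method.items():
            rec = {"N": n, "C": c, "M": m, "method": method}
            rec.update(summarize(reps, truth))
            records.append(rec)
    summaries = summaries_frame(records)
    ranks = rank_methods(summaries)
    return summaries, ranks


def run_grid(cfg: BenchmarkConfig, out_dir: str | Path | None = None,
             calib_n: int = 100_000) -> dict:
    """Execute the whole configured grid and write summary/rank tables."""
    cfg.grid.validate()
    out = Path(out_dir if out_dir is not None else cfg.grid.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calibrator = Calibrator(cfg, calib_n=calib_n)
    scenarios = enumerate_scenarios(cfg.grid)
    all_results = {}
    manifest = RunManifest(config_hash=config_hash(cfg), root_seed=cfg.grid.root_seed)
    for idx, sc in enumerate(scenarios):
        log.info("running scenario %s (%d/%d)", sc.label(), idx + 1, len(scenarios))
        res = run_scenario(sc, cfg.grid.methods, cfg, calibrator, scenario_idx=idx)
        all_results[(sc.n, sc.censor_target, sc.miss_target)] = res
        manifest.scenarios.append({
            "label": sc.label(), "index": idx, "reps": sc.reps,
            "skipped": {m: r.n_skipped for m, r in res.items()}})
    truth = calibrator.truth()
    summaries, ranks = summarize_and_rank(all_results, truth, cfg.grid)
    summaries.to_csv(out / "summaries.csv", index=False)
    ranks.to_csv(out / "ranks.csv", index=False)
    manifest.calibrations = calibrator.summary()
    manifest.outputs = {"summaries": str(out / "summaries.csv"),
                        "ranks": str(out / "ranks.csv"),
                        "reps": cfg.grid.reps}
    manifest.save(out / "manifest.json")
    return {"summaries": summaries, "ranks": ranks,
            "good_counts": good_counts(ranks), "manifest": manifest,
            "results": all_results, "truth": truth}
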