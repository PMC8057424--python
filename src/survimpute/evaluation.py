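"""Summary statistics and method ranking for the simulation benchmark.

Five statistics summarize how well each imputation method preserves the six
Cox analysis-model coefficients across S simulation replicates:

* average absolute proportional bias:  mean_{v,s} |b_vs - b_v| / |b_v|
* average proportional MSE (Rubin's-rules form): per covariate,
  (Qbar_v - b_v)^2 + W_v + (1 + 1/S) B_v, divided by b_v^2 and averaged
* average mean squared prediction error: mean_v (1/S) sum_s (b_vs - b_v)^2
* average MAD: mean_v median_s |b_vs - median_s b_vs|  (no consistency factor)
* minimum 95% probability coverage (mPCOV): min over covariates of the
  fraction of replicates whose Wald interval contains the truth.

Methods are then ranked per statistic within each missingness level, the
modal rank taken across missingness levels, and a modal rank of 1 or 2
counted as "good" performance (30 final rankings per method: 5 statistics
x 6 sample-size/censoring blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATISTICS = ["bias", "mse", "mspe", "mad", "mpcov"]

#: statistics where smaller is better; mPCOV ranks higher-is-better
LOWER_IS_BETTER = {"bias": True, "mse": True, "mspe": True, "mad": True,
                   "mpcov": False}


@dataclass
class TrueParams:
    """True analysis-model coefficients, aligned to the coefficient names."""

    beta: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if (self.beta == 0).any():
            bad = [n for n, b in zip(self.names, self.beta) if b == 0]
            raise ValueError(
                f"zero true coefficient(s) {bad}: proportional statistics are undefined")


@dataclass
class RepResults:
    """Per-replicate coefficient estimates, SEs, and Wald interval bounds."""

    coef: np.ndarray      # S x V
    se: np.ndarray        # S x V
    ci_low: np.ndarray    # S x V
    ci_high: np.ndarray   # S x V
    names: list[str] = field(default_factory=list)
    n_skipped: int = 0

    def __post_init__(self):
        self.coef = np.atleast_2d(np.asarray(self.coef, dtype=float))
        self.se = np.atleast_2d(np.asarray(self.se, dtype=float))
        self.ci_low = np.atleast_2d(np.asarray(self.ci_low, dtype=float))
        self.ci_high = np.atleast_2d(np.asarray(self.ci_high, dtype=float))

    @property
    def S(self) -> int:
        return self.coef.shape[0]


def prop_bias(reps: RepResults, truth: TrueParams) -> float:
    """Average absolute proportional bias over covariates and replicates."""
    dev = np.abs(reps.coef - truth.beta) / np.abs(truth.beta)
    return float(dev.mean())


def rubin_mse(reps: RepResults, truth: TrueParams) -> float:
    """Average proportional MSE with the Rubin's-rules variance combination.

    T_v = W_v + (1 + 1/S) B_v combines the mean within-replicate variance
    W_v = mean(se^2) with the between-replicate variance B_v of the point
    estimates; MSE_v = (Qbar_v - b_v)^2 + T_v, reported as mean_v MSE_v/b_v^2.
    """
    S = reps.S
    if S < 2:
        raise ValueError("rubin_mse needs S >= 2 (between-variance undefined)")
    qbar = reps.coef.mean(axis=0)
    W = (reps.se ** 2).mean(axis=0)
    B = reps.coef.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / S) * B
    mse = (qbar - truth.beta) ** 2 + T
    return float(np.mean(mse / truth.beta ** 2))


def mspe(reps: RepResults, truth: TrueParams) -> float:
    """Average mean squared prediction error about the true coefficients."""
    return float(np.mean((reps.coef - truth.beta) ** 2))


def mad_stat(reps: RepResults) -> float:
    """Average median absolute deviation of the estimates (raw, no 1.4826)."""
    med = np.median(reps.coef, axis=0)
    return float(np.mean(np.median(np.abs(reps.coef - med), axis=0)))


def mpcov(reps: RepResults, truth: TrueParams) -> float:
    """Minimum over covariates of the empirical 95% CI coverage."""
    covered = (reps.ci_low <= truth.beta) & (truth.beta <= reps.ci_high)
    return float(covered.mean(axis=0).min())


def summarize(reps: RepResults, truth: TrueParams) -> dict[str, float]:
    """All five statistics for one scenario/method cell."""
    return {"bias": prop_bias(reps, truth),
            "mse": rubin_mse(reps, truth),
            "mspe": mspe(reps, truth),
            "mad": mad_stat(reps),
            "mpcov": mpcov(reps, truth)}


def summaries_frame(records: list[dict]) -> pd.DataFrame:
    """Long-format table (N, C, M, method, statistic, value)."""
    rows = []
    for rec in records:
        for stat in STATISTICS:
            rows.append({"N": rec["N"], "C": rec["C"], "M": rec["M"],
                         "method": rec["method"], "statistic": stat,
                         "value": rec[stat]})
    return pd.DataFrame(rows)


def _modal_rank(ranks: np.ndarray) -> int:
    """Mode of the per-M ranks; ties resolve to the best (smallest) rank."""
    vals, counts = np.unique(ranks, return_counts=True)
    return int(vals[counts == counts.max()].min())


def rank_methods(summaries: pd.DataFrame) -> pd.DataFrame:
    """Rank methods per statistic within each (N, C) block.

    Within every (N, C, statistic, M) cell the five methods are ranked 1..5
    (ties share the minimum rank); the modal rank across the missingness
    levels gives the final rank, and modal rank <= 2 flags "good"
    performance.  Lower statistic values rank better except mPCOV, where
    higher coverage ranks better.
    """
    required = {"N", "C", "M", "method", "statistic", "value"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    methods = sorted(summaries["method"].unique())
    m_levels = sorted(summaries["M"].unique())
    out_rows = []
    for (N, C, stat), block in summaries.groupby(["N", "C", "statistic"]):
        per_m = {}
        for M, cell in block.groupby("M"):
            missing = set(methods) - set(cell["method"])
            if missing:
                raise ValueError(
                    f"incomplete cell N={N} C={C} M={M} {stat}: missing {sorted(missing)}")
            vals = cell.set_index("method")["value"].reindex(methods)
            per_m[M] = vals.rank(method="min",
                                 ascending=LOWER_IS_BETTER[stat]).astype(int)
        if set(per_m) != set(m_levels):
            raise ValueError(f"block N={N} C={C} {stat} lacks M levels "
                             f"{sorted(set(m_levels) - set(per_m))}")
        for method in methods:
            ranks = np.array([per_m[M][method] for M in m_levels])
            modal = _modal_rank(ranks)
            row = {"N": N, "C": C, "statistic": stat, "method": method,
                   "modal_rank": modal, "good": modal <= 2}
            for M, r in zip(m_levels, ranks):
                row[f"rank_M{int(round(M * 100))}"] = int(r)
            out_rows.append(row)
    return pd.DataFrame(out_rows)


def good_counts(rank_table: pd.DataFrame) -> pd.Series:
    """Times each method ranked 1st or 2nd out of its 30 final rankings."""
    return rank_table.groupby("method")["good"].sum().astype(int)
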