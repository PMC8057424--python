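"""Summary-statistic and ranking tests, including hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import survimpute as si
from survimpute.evaluation import STATISTICS, _modal_rank


def reps_from(coef, se=None, z=1.959964):
    coef = np.atleast_2d(np.asarray(coef, float))
    se = np.full_like(coef, 0.1) if se is None else np.atleast_2d(np.asarray(se, float))
    return si.RepResults(coef=coef, se=se,
                         ci_low=coef - z * se, ci_high=coef + z * se)


def truth1(b=1.0):
    return si.TrueParams(beta=[b], names=["x"])


class TestStatisticsHandExamples:
    def test_prop_bias(self):
        reps = reps_from([[1.0], [1.2]])
        assert si.prop_bias(reps, truth1()) == pytest.approx(0.1, abs=1e-12)

    def test_prop_bias_homogeneity(self):
        base = reps_from([[1.0], [1.2]])
        doubled = reps_from([[1.0], [1.4]])  # deviations 0, 0.4
        assert si.prop_bias(doubled, truth1()) == pytest.approx(
            2 * si.prop_bias(base, truth1()), abs=1e-12)

    def test_rubin_mse_hand_computation(self):
        """Qbar=1.1, W=0.01, B=0.02, T=0.01+1.5*0.02=0.04, MSE=0.05."""
        reps = reps_from([[1.0], [1.2]], [[0.1], [0.1]])
        assert si.rubin_mse(reps, truth1()) == pytest.approx(0.05, abs=1e-12)

    def test_rubin_mse_degenerate_cases(self):
        perfect = reps_from([[1.0], [1.0]], [[0.0], [0.0]])
        assert si.rubin_mse(perfect, truth1()) == pytest.approx(0.0, abs=1e-15)
        # B = 0: MSE reduces to bias^2 + W exactly
        shifted = reps_from([[1.3], [1.3]], [[0.2], [0.2]])
        assert si.rubin_mse(shifted, truth1()) == pytest.approx(0.09 + 0.04, abs=1e-12)

    def test_rubin_mse_needs_two_reps(self):
        with pytest.raises(ValueError, match="S >= 2"):
            si.rubin_mse(reps_from([[1.0]]), truth1())

    def test_mspe_hand_computation(self):
        reps = reps_from([[1.0], [1.2]])
        assert si.mspe(reps, truth1()) == pytest.approx(0.02, abs=1e-12)

    def test_mspe_lower_bound_by_squared_bias(self):
        reps = reps_from([[0.9], [1.3]])
        signed = np.mean([0.9, 1.3]) - 1.0
        assert si.mspe(reps, truth1()) >= signed ** 2

    def test_mad_hand_computation(self):
        reps = reps_from([[1.0], [1.2], [1.4]])
        assert si.mad_stat(reps) == pytest.approx(0.2, abs=1e-12)

    def test_mad_location_invariance(self):
        reps = reps_from([[1.0], [1.2], [1.4]])
        shifted = reps_from([[6.0], [6.2], [6.4]])
        assert si.mad_stat(shifted) == pytest.approx(si.mad_stat(reps), abs=1e-12)

    def test_mpcov_direct_count(self):
        coef = np.array([[1.0], [1.0], [1.0], [5.0]])
        reps = reps_from(coef, np.full_like(coef, 0.1))
        assert si.mpcov(reps, truth1()) == pytest.approx(0.75, abs=1e-12)

    def test_mpcov_min_not_mean(self):
        coef = np.array([[1.0, 9.0], [1.0, 9.0]])
        reps = reps_from(coef, np.full_like(coef, 0.1))
        t = si.TrueParams(beta=[1.0, 1.0], names=["a", "b"])
        assert si.mpcov(reps, t) == 0.0

    def test_perfect_estimator_degenerate_input(self):
        reps = reps_from([[1.0, 2.0], [1.0, 2.0]], np.full((2, 2), 1e-9))
        t = si.TrueParams(beta=[1.0, 2.0], names=["a", "b"])
        assert si.prop_bias(reps, t) == 0.0
        assert si.mspe(reps, t) == 0.0
        assert si.mad_stat(reps) == 0.0
        assert si.mpcov(reps, t) == 1.0

    def test_zero_truth_guard(self):
        with pytest.raises(ValueError, match="zero"):
            si.TrueParams(beta=[1.0, 0.0], names=["a", "b"])


coef_mats = hnp.arrays(np.float64, st.tuples(st.integers(3, 8), st.integers(1, 4)),
                       elements=st.floats(-3, 3, allow_nan=False))


class TestStatisticProperties:
    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(coef=coef_mats, perm_seed=st.integers(0, 1000))
    def test_replicate_permutation_invariance(self, coef, perm_seed):
        V = coef.shape[1]
        truth = si.TrueParams(beta=np.ones(V), names=[f"x{i}" for i in range(V)])
        order = np.random.default_rng(perm_seed).permutation(coef.shape[0])
        a, b = reps_from(coef), reps_from(coef[order])
        for stat in (si.prop_bias, si.mspe):
            assert stat(a, truth) == pytest.approx(stat(b, truth), rel=1e-12)
        assert si.mad_stat(a) == pytest.approx(si.mad_stat(b), rel=1e-12)
        assert si.rubin_mse(a, truth) == pytest.approx(si.rubin_mse(b, truth), rel=1e-9)
        assert si.mpcov(a, truth) == si.mpcov(b, truth)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(coef=coef_mats)
    def test_rubin_mse_dominates_squared_proportional_bias(self, coef):
        V = coef.shape[1]
        truth = si.TrueParams(beta=np.ones(V), names=[f"x{i}" for i in range(V)])
        reps = reps_from(coef)
        qbar = coef.mean(axis=0)
        comp = np.mean((qbar - truth.beta) ** 2 / truth.beta ** 2)
        assert si.rubin_mse(reps, truth) >= comp - 1e-12


def make_summaries(values_by_method, n=200, c=0.3, m_levels=(0.05, 0.10, 0.15)):
    """values_by_method: method -> per-M dict of the five statistics."""
    rows = []
    for method, per_m in values_by_method.items():
        for m, stats in per_m.items():
            for stat, v in stats.items():
                rows.append({"N": n, "C": c, "M": m, "method": method,
                             "statistic": stat, "value": v})
    return pd.DataFrame(rows)


class TestRankMethods:
    def grid_values(self, order, m_levels=(0.05, 0.10, 0.15)):
        """Strictly ordered statistic values following ``order`` at every M."""
        vals = {}
        for i, method in enumerate(order):
            per_m = {}
            for m in m_levels:
                per_m[m] = {s: 0.1 * (i + 1) for s in STATISTICS if s != "mpcov"}
                per_m[m]["mpcov"] = 0.95 - 0.05 * i  # higher coverage is better
            vals[method] = per_m
        return vals

    def test_strict_order_gives_ranks_1_to_5(self):
        order = ["GLM", "LASSO", "MARS", "SVM", "RF"]
        ranks = si.rank_methods(make_summaries(self.grid_values(order)))
        for stat in STATISTICS:
            block = ranks[ranks["statistic"] == stat].set_index("method")
            assert [block.loc[m, "modal_rank"] for m in order] == [1, 2, 3, 4, 5]

    def test_modal_rank_majority_and_tie_rule(self):
        assert _modal_rank(np.array([1, 1, 2])) == 1
        assert _modal_rank(np.array([3, 3, 2])) == 3
        assert _modal_rank(np.array([1, 2, 3])) == 1  # all tied: best wins

    def test_good_flag_threshold(self):
        order = ["A", "B", "C", "D", "E"]
        ranks = si.rank_methods(make_summaries(self.grid_values(order)))
        good = si.good_counts(ranks)
        assert good["A"] == 5 and good["B"] == 5
        assert good["C"] == good["D"] == good["E"] == 0

    def test_relabeling_equivariance(self):
        order = ["A", "B", "C", "D", "E"]
        base = si.rank_methods(make_summaries(self.grid_values(order)))
        swapped = si.rank_methods(make_summaries(self.grid_values(
            ["B", "A", "C", "D", "E"])))
        a = base.set_index(["statistic", "method"])["modal_rank"]
        b = swapped.set_index(["statistic", "method"])["modal_rank"]
        for stat in STATISTICS:
            assert a[(stat, "A")] == b[(stat, "B")]
            assert a[(stat, "B")] == b[(stat, "A")]

    def test_ties_share_minimum_rank(self):
        vals = self.grid_values(["A", "B", "C", "D", "E"])
        for m in (0.05, 0.10, 0.15):  # A and B tie everywhere
            vals["B"][m] = dict(vals["A"][m])
        ranks = si.rank_methods(make_summaries(vals))
        bias = ranks[ranks["statistic"] == "bias"].set_index("method")
        assert bias.loc["A", "modal_rank"] == bias.loc["B", "modal_rank"] == 1
        assert bias.loc["C", "modal_rank"] == 3

    def test_incomplete_cell_raises(self):
        vals = self.grid_values(["A", "B", "C", "D", "E"])
        df = make_summaries(vals)
        df = df[~((df["method"] == "E") & (df["M"] == 0.15))]
        with pytest.raises(ValueError, match="incomplete"):
            si.rank_methods(df)

    def test_full_grid_has_thirty_rankings_per_method(self):
        frames = []
        for n in (200, 500, 1000):
            for c in (0.10, 0.30):
                frames.append(make_summaries(
                    self.grid_values(["A", "B", "C", "D", "E"]), n=n, c=c))
        ranks = si.rank_methods(pd.concat(frames, ignore_index=True))
        counts = ranks.groupby("method").size()
        assert (counts == 30).all()  # 5 statistics x 6 (N, C) blocks
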