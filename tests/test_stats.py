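import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from cnaburden import (associate, bh_adjust, compare_regions,
                       fisher_exact_rxc, km_logrank, median_split)
from cnaburden.errors import ValidationError
from cnaburden.profiles import ProfileMatrix, WindowSet


def make_profile(values, ids=None):
    n_win = values.shape[1]
    win = pd.DataFrame({
        "window_id": [f"w{i}" for i in range(n_win)],
        "chrom": ["c"] * n_win,
        "start": np.arange(n_win) * 100 + 1,
        "end": np.arange(n_win) * 100 + 100,
    })
    ws = WindowSet(kind="fixed", windows=win, fixed_width=100)
    means = pd.DataFrame(values, columns=ws.ids,
                         index=ids or [f"S{i}" for i in range(len(values))])
    return ProfileMatrix(means=means, windows=ws)


class TestAssociate:
    def test_separated_binary_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(np.r_[rng.normal(0, 1, 50), rng.normal(3, 1, 50)],
                           index=[f"S{i}" for i in range(100)])
        var = pd.Series(["a"] * 50 + ["b"] * 50, index=scores.index)
        res = associate(scores, var)
        assert res.test_parametric == "t_test"
        assert res.test_nonparametric == "wilcoxon_rank_sum"
        assert res.p_parametric < 1e-6 and res.p_nonparametric < 1e-6

    def test_numeric_variable_identical_to_score(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        res = associate(scores, scores.copy())
        assert res.kind == "numeric"
        assert res.group_summaries.loc["pearson_r", "coefficient"] == \
            pytest.approx(1.0)

    def test_three_level_variable_uses_anova_and_kruskal(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(0, 1, 60),
                           index=[f"S{i}" for i in range(60)])
        var = pd.Series(["a", "b", "c"] * 20, index=scores.index)
        res = associate(scores, var)
        assert res.test_parametric == "anova"
        assert res.test_nonparametric == "kruskal_wallis"

    def test_anova_p_uniform_under_null(self):
        """Type-I calibration: null ANOVA p-values are ~Uniform(0,1)."""
        rng = np.random.default_rng(2)
        idx = [f"S{i}" for i in range(45)]
        var = pd.Series(["a", "b", "c"] * 15, index=idx)
        pvals = []
        for _ in range(400):
            scores = pd.Series(rng.normal(0, 1, 45), index=idx)
            pvals.append(associate(scores, var).p_parametric)
        ks = sps.kstest(pvals, "uniform").pvalue
        assert ks > 0.01

    def test_small_level_dropped_single_level_errors(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        var = pd.Series(["x", "x", "x", "y"], index=scores.index)
        with pytest.warns(UserWarning, match="<2 samples"):
            with pytest.raises(ValidationError, match="single level"):
                associate(scores, var)


class TestBhAdjust:
    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert bh_adjust([]).size == 0

    def test_never_decreases_and_preserves_rejection_monotonicity(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestFisher:
    def test_matches_scipy_on_all_small_2x2_tables(self):
        worst = 0.0
        for a in range(8):
            for b in range(8 - a):
                for c in range(8):
                    for d in range(8 - c):
                        t = np.array([[a, b], [c, d]])
                        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                            continue
                        mine = fisher_exact_rxc(t)
                        ref = sps.fisher_exact(t)[1]
                        worst = max(worst, abs(mine - ref))
        assert worst < 1e-9

    def test_known_2x2(self):
        assert fisher_exact_rxc([[8, 2], [1, 9]]) == pytest.approx(
            sps.fisher_exact([[8, 2], [1, 9]])[1])

    def test_monte_carlo_fallback_close_to_exact(self):
        t = [[10, 2, 8], [3, 9, 5]]
        exact = fisher_exact_rxc(t)
        mc = fisher_exact_rxc(t, max_exact_total=1, n_sim=40_000, rng=0)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_degenerate_tables(self):
        assert fisher_exact_rxc([[5, 0], [0, 0]]) == 1.0
        assert fisher_exact_rxc([[3, 3], [3, 3]]) == 1.0


class TestCompareRegions:
    def test_shifted_window_detected(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 0.02, size=(20, 5))
        vals[:10, 2] += 0.5  # group A gains window w2
        prof = make_profile(vals)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=prof.means.index)
        res = compare_regions(prof, groups, mode="t_test")
        hit = res[res["window_id"] == "w2"].iloc[0]
        assert hit["adj_p_value"] < 0.01
        assert hit["significant"]

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, size=(40, 1000))
        prof = make_profile(vals)
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=prof.means.index)
        res = compare_regions(prof, groups, mode="t_test", adjust=False,
                              alpha=0.1)
        rate = (res["p_value"] < 0.1).mean()
        se = np.sqrt(0.1 * 0.9 / 1000)
        assert abs(rate - 0.1) <= 2 * se

    def test_fisher_mode_contingency(self):
        vals = np.zeros((20, 3))
        vals[:10, 0] = 0.5   # group A gains w0
        prof = make_profile(vals)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=prof.means.index)
        res = compare_regions(prof, groups, mode="fisher", seed=0)
        w0 = res[res["window_id"] == "w0"].iloc[0]
        assert w0["p_value"] < 0.001
        neutral = res[res["window_id"] == "w1"].iloc[0]
        assert neutral["p_value"] == 1.0

    def test_pairwise_comparisons_for_three_groups(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, size=(18, 4))
        prof = make_profile(vals)
        groups = pd.Series(["A", "B", "C"] * 6, index=prof.means.index)
        res = compare_regions(prof, groups, mode="t_test")
        pairs = set(map(tuple, res[["group_a", "group_b"]].values))
        assert pairs == {("A", "B"), ("A", "C"), ("B", "C")}
        assert len(res) == 3 * 4

    def test_degenerate_equal_constant_window_p_one(self):
        vals = np.zeros((10, 2))
        prof = make_profile(vals)
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=prof.means.index)
        res = compare_regions(prof, groups, mode="t_test", adjust=False)
        assert (res["p_value"] == 1.0).all()


class TestSurvival:
    def test_product_limit_steps(self):
        res = km_logrank([1, 2, 3], [1, 1, 1], ["g", "g", "g"])
        surv = res.curves["g"].iloc[:, 0]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_identical_groups_logrank_near_one(self):
        rng = np.random.default_rng(7)
        times = np.r_[rng.exponential(10, 300), rng.exponential(10, 300)]
        events = np.ones(600, dtype=int)
        groups = ["A"] * 300 + ["B"] * 300
        res = km_logrank(times, events, groups)
        assert res.logrank_p > 0.05

    def test_all_censored_skips_test(self):
        with pytest.warns(UserWarning, match="skipped"):
            res = km_logrank([5, 6, 7, 8], [0, 0, 0, 0], list("abab"))
        assert res.logrank_p is None
        for curve in res.curves.values():
            assert (curve.values == 1.0).all()

    def test_median_split(self):
        v = pd.Series([1, 2, 3, 10], index=list("abcd"), name="bcs")
        labels = median_split(v)
        assert labels.nunique() == 2
        assert (labels.iloc[:2] == labels.iloc[0]).all()
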