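import numpy as np
import pandas as pd
import pytest

from cnaburden import (call_states, cluster, correlate_profiles, frequencies,
                       make_windows, profile_cohort, profile_sample)
from cnaburden.errors import ConfigError
from cnaburden.profiles import ProfileMatrix
from tests.conftest import make_table


class TestWindows:
    def test_arm_windows_flank_centromere(self, toy):
        ws = make_windows(toy, "arm")
        assert len(ws) == 6
        w = ws.windows
        chr1 = w[w["chrom"] == "chr1"]
        assert chr1.iloc[0]["end"] == 38_500_000
        assert chr1.iloc[1]["start"] == 41_500_001

    def test_half_arm_split_at_midpoint(self, toy):
        ws = make_windows(toy, "half_arm")
        assert len(ws) == 12
        first, second = ws.windows.iloc[0], ws.windows.iloc[1]
        assert first["end"] + 1 == second["start"]
        assert abs((first["end"] - first["start"]) -
                   (second["end"] - second["start"])) <= 1

    def test_fixed_windows_truncate_last_tile(self, toy):
        ws = make_windows(toy, "fixed", 5_000_000)
        chr1p = ws.windows[(ws.windows["chrom"] == "chr1")
                           & ws.windows["window_id"].str.startswith("1p")]
        lengths = (chr1p["end"] - chr1p["start"] + 1).tolist()
        assert lengths[:-1] == [5_000_000] * (len(lengths) - 1)
        assert lengths[-1] == 38_500_000 - 5_000_000 * (len(lengths) - 1)

    def test_fixed_width_must_be_allowed(self, toy):
        with pytest.raises(ConfigError, match="fixed_width"):
            make_windows(toy, "fixed", 7_000_000)

    def test_sub_cytoband_count_matches_band_rows(self):
        from cnaburden import load_genome
        genome = load_genome("hg19")
        ws = make_windows(genome, "sub_cytoband")
        bands = genome.cytobands
        non_acen_chr21 = bands[(bands["chrom"] == "chr21")
                               & (bands["stain"] != "acen")]
        got = ws.windows[ws.windows["chrom"] == "chr21"]
        assert len(got) == len(non_acen_chr21)

    def test_cytoband_windows_merge_sub_bands(self):
        from cnaburden import load_genome
        genome = load_genome("hg19")
        sub = make_windows(genome, "sub_cytoband")
        major = make_windows(genome, "cytoband")
        assert len(major) < len(sub)
        assert not any("." in wid for wid in major.ids)

    def test_windows_tile_arms_without_overlap(self, toy):
        for kind in ("arm", "half_arm", "cytoband", "sub_cytoband"):
            ws = make_windows(toy, kind)
            for _, sub in ws.windows.groupby("chrom"):
                sub = sub.sort_values("start")
                assert (sub["start"].values[1:] > sub["end"].values[:-1]).all()


class TestProfileValues:
    def test_fully_covered_window_takes_segment_mean(self, toy):
        ws = make_windows(toy, "arm")
        segs = make_table([("S", "chr1", 1, 100_000_000, 0.5)]).segments
        w = profile_sample(segs, ws)
        assert w[0] == pytest.approx(0.5)
        assert w[1] == pytest.approx(0.5)

    def test_half_covered_window_weighted_mean(self, toy):
        ws = make_windows(toy, "arm")
        half = 38_500_000 // 2
        segs = make_table([
            ("S", "chr1", 1, half, 0.4),
            ("S", "chr1", half + 1, 38_500_000, 0.0),
        ]).segments
        w = profile_sample(segs, ws)
        assert w[0] == pytest.approx(0.2, abs=1e-6)

    def test_uncovered_bp_contribute_zero(self, toy):
        ws = make_windows(toy, "arm")
        covered = int(38_500_000 * 0.3)
        segs = make_table([("S", "chr1", 1, covered, 1.0)]).segments
        w = profile_sample(segs, ws)
        assert w[0] == pytest.approx(0.3, abs=1e-6)

    def test_linearity_in_segment_means(self, toy, cohort):
        table, _ = cohort
        ws = make_windows(toy, "half_arm")
        sid = table.samples[0]
        segs = table.segments[table.segments["sample_id"] == sid]
        w1 = profile_sample(segs, ws)
        scaled = segs.assign(seg_mean=segs["seg_mean"] * 3.0)
        assert np.allclose(profile_sample(scaled, ws), 3.0 * w1)

    def test_window_means_match_bp_level_oracle(self):
        """W equals a literal per-base-pair average on a miniature genome."""
        from cnaburden.profiles import WindowSet

        win_df = pd.DataFrame(
            {"window_id": ["w1", "w2", "w3"], "chrom": ["c"] * 3,
             "start": [1, 101, 201], "end": [100, 200, 260]})
        ws = WindowSet(kind="fixed", windows=win_df, fixed_width=100)
        rng = np.random.default_rng(3)
        for _ in range(25):
            segs = []
            pos = 1
            while pos < 260:
                end = int(min(pos + rng.integers(1, 80), 260))
                if rng.random() < 0.7:
                    segs.append(("S", "c", pos, end,
                                 float(rng.normal(0, 1))))
                pos = end + 1 + int(rng.integers(0, 20))
            if not segs:
                continue
            seg_df = make_table(segs).segments
            got = profile_sample(seg_df, ws)
            # bp-level oracle: value of the covering segment at each base
            bp = {}
            for _, row in seg_df.iterrows():
                for p in range(row["start"], row["end"] + 1):
                    bp[p] = row["seg_mean"]
            for i, w in enumerate(win_df.itertuples()):
                length = w.end - w.start + 1
                want = sum(bp.get(p, 0.0)
                           for p in range(w.start, w.end + 1)) / length
                assert got[i] == pytest.approx(want, abs=1e-12)


class TestStatesAndFrequencies:
    def make_profile(self, values, toy):
        ws = make_windows(toy, "arm")
        means = pd.DataFrame(values, columns=ws.ids)
        means.index = [f"S{i}" for i in range(len(means))]
        return ProfileMatrix(means=means, windows=ws)

    def test_state_cutoffs_inclusive(self, toy):
        prof = self.make_profile([[0.25, -0.2, 0.0, 0.19, -0.19, 0.2]], toy)
        states = call_states(prof)
        assert states.iloc[0].tolist() == [
            "gain", "loss", "neutral", "neutral", "neutral", "gain"]

    def test_bad_cutoffs_rejected(self, toy):
        prof = self.make_profile([[0.0] * 6], toy)
        prof.gain_cut, prof.loss_cut = -0.1, 0.1
        with pytest.raises(ConfigError):
            call_states(prof)

    def test_frequencies_percentages(self, toy):
        prof = self.make_profile(
            [[0.5] * 6, [0.5] * 6, [0.0] * 6, [-0.5] * 6], toy)
        per_window, per_sample = frequencies(call_states(prof))
        assert per_window["gain_pct"].tolist() == [50.0] * 6
        assert per_window["loss_pct"].tolist() == [25.0] * 6
        assert per_sample["gained_windows"].tolist() == [6, 6, 0, 0]
        assert ((per_window["gain_pct"] + per_window["loss_pct"]) <= 100).all()


class TestCorrelationAndClustering:
    def test_identical_profiles_correlate_perfectly(self, toy):
        prof = TestStatesAndFrequencies().make_profile(
            [[0.5, 0.1, -0.3, 0.0, 0.2, -0.1]] * 2, toy)
        corr = correlate_profiles(prof)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert np.diag(corr) == pytest.approx(1.0)

    def test_anticorrelated_profiles(self, toy):
        base = [0.5, 0.1, -0.3, 0.0, 0.2, -0.1]
        prof = TestStatesAndFrequencies().make_profile(
            [base, [-x for x in base]], toy)
        corr = correlate_profiles(prof, method="pearson")
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_profile_marked_undefined(self, toy):
        prof = TestStatesAndFrequencies().make_profile(
            [[0.0] * 6, [0.5, 0.1, -0.3, 0.0, 0.2, -0.1],
             [0.1, 0.5, -0.2, 0.1, 0.0, -0.4]], toy)
        corr = correlate_profiles(prof)
        assert np.isnan(corr.iloc[0, 1])
        assert corr.iloc[0, 0] == 1.0

    def test_group_axis_averages_members(self, toy, cohort):
        table, _ = cohort
        ws = make_windows(toy, "arm")
        prof = profile_cohort(table, ws)
        groups = pd.Series(["A" if i % 2 else "B"
                            for i in range(len(prof.samples))],
                           index=prof.means.index)
        corr = correlate_profiles(prof, axis="groups", groups=groups)
        assert corr.shape == (2, 2)

    def test_identical_items_merge_first(self, toy):
        base = [0.5, 0.1, -0.3, 0.0, 0.2, -0.1]
        other = [-0.4, 0.3, 0.6, -0.2, 0.1, 0.9]
        prof = TestStatesAndFrequencies().make_profile(
            [base, base, other], toy)
        res = cluster(correlate_profiles(prof))
        # the two identical samples are adjacent leaves
        order = res.leaf_order
        assert abs(order.index("S0") - order.index("S1")) == 1
        assert res.newick.endswith(";")

    def test_dendrogram_invariant_under_permutation(self, toy):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.5, size=(6, 6))
        prof = TestStatesAndFrequencies().make_profile(values, toy)
        corr = correlate_profiles(prof)
        res1 = cluster(corr)
        perm = rng.permutation(6)
        corr2 = corr.iloc[perm, perm]
        res2 = cluster(corr2)
        # same merge heights regardless of input order
        assert np.allclose(sorted(res1.linkage[:, 2]),
                           sorted(res2.linkage[:, 2]))

    def test_single_item_tree(self, toy):
        ws = make_windows(toy, "arm")
        means = pd.DataFrame([[0.1] * 6], columns=ws.ids, index=["only"])
        res = cluster(pd.DataFrame([[1.0]], index=["only"], columns=["only"]))
        assert res.newick == "only;"
        assert res.leaf_order == ["only"]

    def test_nan_correlations_imputed_with_warning(self):
        corr = pd.DataFrame([[1.0, np.nan, 0.2], [np.nan, 1.0, 0.1],
                             [0.2, 0.1, 1.0]],
                            index=list("abc"), columns=list("abc"))
        with pytest.warns(UserWarning, match="imputed"):
            res = cluster(corr)
        assert len(res.leaf_order) == 3


def test_scope_filtered_profiles(toy, cohort):
    table, truth = cohort
    ws = make_windows(toy, "arm")
    broad = profile_cohort(table, ws, "broad", toy)
    focal = profile_cohort(table, ws, "focal", toy)
    full = profile_cohort(table, ws, "all")
    assert broad.means.shape == full.means.shape == focal.means.shape
    # focal-only profiles have smaller magnitude on arm windows than broad
    assert focal.means.abs().values.sum() < broad.means.abs().values.sum()
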