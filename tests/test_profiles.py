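"""Migration profiles, Welch test, profile distance and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from comprof import (ComplexomeMatrix, DifferentialAbundanceModel, SampleDesign,
                     amplitude_adjusted_distance, cluster_order, detection_count,
                     group_mean_profile, max_scale, welch_from_sums,
                     welch_total_abundance_test)

from conftest import random_matrix


class TestGroupMeanProfile:
    def test_analytically_forced_mean(self, small_matrix):
        gp = group_mean_profile(small_matrix, "WT", "P1")
        np.testing.assert_array_equal(gp.mean, [2, 3, 4])
        assert gp.n_replicates == 2

    def test_identical_replicates_have_zero_sd(self, small_matrix):
        gp = group_mean_profile(small_matrix, "WT", "P2")
        np.testing.assert_array_equal(gp.mean, [1, 1, 1])
        np.testing.assert_array_equal(gp.sd, [0, 0, 0])

    def test_matches_brute_force_mean_and_sd(self, design_3x3):
        rng = np.random.default_rng(21)
        values = rng.uniform(0, 5, size=(1, 4, 6))
        m = ComplexomeMatrix(["P"], 4, design_3x3, values)
        gp = group_mean_profile(m, "lpa2", "P")
        for k in range(4):
            reps = [m.intensity("P", k + 1, s) for s in m.design.samples_of("lpa2")]
            assert gp.mean[k] == pytest.approx(np.mean(reps))
            assert gp.sd[k] == pytest.approx(np.std(reps, ddof=1))

    def test_unknown_group_raises(self, small_matrix):
        with pytest.raises(KeyError):
            group_mean_profile(small_matrix, "nope", "P1")


class TestMaxScale:
    @pytest.mark.parametrize("vec,expected", [
        ([0, 2, 4], [0, 0.5, 1]),
        ([0, 0, 0], [0, 0, 0]),
        ([5], [1]),
    ])
    def test_examples(self, vec, expected):
        np.testing.assert_allclose(max_scale(np.array(vec, float)), expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(float, st.integers(2, 20),
                  elements=st.floats(0, 1e6, allow_nan=False)))
    def test_idempotent_and_peak_one(self, vec):
        once = max_scale(vec)
        np.testing.assert_array_equal(max_scale(once), once)
        if vec.max() > 0:
            assert once.max() == 1.0


class TestDetectionCount:
    def test_zero_in_one_replicate(self, design_3x3):
        values = np.ones((1, 2, 6))
        values[0, :, 1] = 0          # WT replicate 2 all-zero
        m = ComplexomeMatrix(["P"], 2, design_3x3, values)
        assert detection_count(m, "WT", "P") == 2
        assert detection_count(m, "lpa2", "P") == 3

    def test_all_zero_gives_zero(self, design_3x3):
        m = ComplexomeMatrix(["P"], 2, design_3x3, np.zeros((1, 2, 6)))
        assert detection_count(m, "WT", "P") == 0

    def test_matches_brute_force_on_random_dropout(self, design_3x3):
        rng = np.random.default_rng(31)
        values = rng.uniform(0, 1, size=(1, 5, 6))
        values[rng.random(values.shape) < 0.5] = 0
        m = ComplexomeMatrix(["P"], 5, design_3x3, values)
        for g in ("WT", "lpa2"):
            brute = sum(
                1 for s in m.design.samples_of(g)
                if sum(m.intensity("P", k + 1, s) for k in range(5)) > 0)
            assert detection_count(m, g, "P") == brute


class TestWelch:
    def test_frozen_worked_example(self):
        # hand-evaluated via the Welch formula, cross-checked with scipy
        t, df, p = welch_from_sums([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674234614174767, abs=1e-12)
        assert df == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(0.021311641128756713, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        t, _, p = welch_from_sums([2, 2, 3], [2, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_equal_means_convention(self):
        t, _, p = welch_from_sums([2, 2], [2, 2])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_from_sums([3, 3], [2, 2])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_swapping_groups_negates_t_preserves_p(self):
        rng = np.random.default_rng(41)
        a, b = rng.uniform(0, 10, 3), rng.uniform(0, 10, 3)
        t1, df1, p1 = welch_from_sums(a, b)
        t2, df2, p2 = welch_from_sums(b, a)
        assert t1 == pytest.approx(-t2) and df1 == df2 and p1 == pytest.approx(p2)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            welch_from_sums([1], [2, 3])

    def test_agrees_with_scipy_on_1000_random_inputs(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            a = rng.normal(10, 2, 3)
            b = rng.normal(10, 3, 3)
            t, df, p = welch_from_sums(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_total_abundance_test_uses_slice_sums(self, small_matrix):
        res = welch_total_abundance_test(small_matrix, "P1", "WT", "lpa2")
        np.testing.assert_array_equal(res.sums_a, [6, 12])
        np.testing.assert_array_equal(res.sums_b, [6, 0])
        t, df, p = welch_from_sums([6, 12], [6, 0])
        assert res.welch_t == t and res.p_value == p

    def test_lognormal_null_is_conservative_and_identical_to_scipy(self):
        # On skewed log-normal replicate sums at n=3 the Welch test rejects
        # below the nominal 5% level; this is a property of the test, not of
        # this implementation — scipy yields bit-identical p-values.
        rng = np.random.default_rng(99)
        ps_ours, ps_scipy = [], []
        for _ in range(500):
            a = rng.lognormal(0, 0.2, 3)
            b = rng.lognormal(0, 0.2, 3)
            ps_ours.append(welch_from_sums(a, b)[2])
            ps_scipy.append(stats.ttest_ind(a, b, equal_var=False).pvalue)
        np.testing.assert_allclose(ps_ours, ps_scipy, atol=1e-12)
        rate = np.mean(np.array(ps_ours) < 0.05)
        assert rate < 0.06          # never anti-conservative here


class TestAmplitudeAdjustedDistance:
    def test_analytically_forced(self):
        assert amplitude_adjusted_distance([0, 2, 0], [0, 1, 0]) == pytest.approx(0.5)

    def test_zero_iff_identical(self):
        a = np.array([1.0, 2.0, 0.0])
        assert amplitude_adjusted_distance(a, a) == 0.0
        assert amplitude_adjusted_distance(a, a + [0, 0, 1]) > 0

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(17)
        a, b = rng.uniform(0, 5, 10), rng.uniform(0, 5, 10)
        d = amplitude_adjusted_distance(a, b)
        assert amplitude_adjusted_distance(b, a) == pytest.approx(d, abs=1e-12)
        assert amplitude_adjusted_distance(10 * a, 10 * b) == pytest.approx(d, abs=1e-12)

    def test_sup_norm_bound(self):
        # |a_k - b_k| <= max(max a, max b) pointwise, so d <= sqrt(S)
        rng = np.random.default_rng(19)
        for _ in range(50):
            S = rng.integers(2, 30)
            a, b = rng.uniform(0, 9, S), rng.uniform(0, 9, S)
            assert amplitude_adjusted_distance(a, b) <= np.sqrt(S) + 1e-12

    def test_both_all_zero_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            amplitude_adjusted_distance([0, 0], [0, 0])


class TestClusterOrder:
    def test_identical_pair_adjacent(self):
        profiles = np.array([[1, 0, 0, 0],
                             [0, 0, 0, 1.0],
                             [1, 0, 0, 0]])
        order = cluster_order(profiles, ["a", "b", "c"])
        ia, ic = order.index("a"), order.index("c")
        assert abs(ia - ic) == 1

    def test_singleton(self):
        assert cluster_order(np.array([[1.0, 2.0]]), ["only"]) == ["only"]

    def test_two_peak_positions_form_contiguous_blocks(self):
        rng = np.random.default_rng(23)
        S = 20
        rows, ids = [], []
        for i in range(10):
            center = 4 if i < 5 else 15
            k = np.arange(S)
            rows.append(np.exp(-((k - center) ** 2) / 2) * rng.uniform(0.5, 2))
            ids.append(f"g{'A' if i < 5 else 'B'}{i}")
        order = cluster_order(np.array(rows), ids)
        labels = ["A" if x.startswith("gA") else "B" for x in order]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_permutation_invariant_up_to_tie_break(self):
        rng = np.random.default_rng(29)
        mat = rng.uniform(0, 1, size=(6, 8))
        ids = [f"p{i}" for i in range(6)]
        order = cluster_order(mat, ids)
        perm = [3, 1, 5, 0, 2, 4]
        order_p = cluster_order(mat[perm], [ids[i] for i in perm])
        assert set(order) == set(order_p)
        # rerunning on identical input is deterministic
        assert cluster_order(mat, ids) == order
        assert cluster_order(mat[perm], [ids[i] for i in perm]) == order_p


class TestModelResults:
    def test_fit_produces_frame_and_summary(self, design_3x3):
        rng = np.random.default_rng(50)
        m = random_matrix(rng, n_proteins=6, n_slices=8, design=design_3x3)
        res = DifferentialAbundanceModel(m, "WT", "lpa2").fit()
        assert set(res.frame.columns) >= {"welch_t", "welch_df", "p_value",
                                          "distance", "p_adj_bh"}
        assert len(res.frame) == 6
        assert ((res.frame["p_value"] >= 0) & (res.frame["p_value"] <= 1)).all()
        text = res.summary()
        assert "WT" in text and "lpa2" in text and "proteins tested" in text

    def test_bh_adjustment_is_monotone_in_p(self, design_3x3):
        rng = np.random.default_rng(51)
        m = random_matrix(rng, n_proteins=10, n_slices=5, design=design_3x3)
        f = DifferentialAbundanceModel(m, "WT", "lpa2").fit().frame
        f = f.dropna(subset=["p_adj_bh"]).sort_values("p_value")
        assert (np.diff(f["p_adj_bh"]) >= -1e-12).all()
        assert (f["p_adj_bh"] >= f["p_value"] - 1e-12).all()

    def test_unknown_group_rejected(self, small_matrix):
        with pytest.raises(KeyError):
            DifferentialAbundanceModel(small_matrix, "WT", "mut")
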