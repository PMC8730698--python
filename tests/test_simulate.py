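"""Synthetic complexome generator: expectations, noise, scenarios."""

import numpy as np
import pytest

from comprof import (AssemblyState, ProteinTruth, SampleDesign, SyntheticTruth,
                     band_ratio_panel, default_study_scenario, expected_profile,
                     filter_proteotypic, normalize, null_scenario,
                     simulate_experiment, study_bands, study_catalog,
                     welch_total_abundance_test)
from comprof.simulate import truth_from_dict, truth_frame

TRUTH_MULTIPLIERS = {"SC": 0.07, "dimer": 0.27, "monomer": 0.60, "RC47": 6.05}


def _single_state_truth(**kw):
    st = AssemblyState("s", center_slice=kw.pop("center", 10),
                       width=kw.pop("width", 1.0),
                       occupancy=kw.pop("occupancy", {"G": 1.0}))
    pt = ProteinTruth("P", amplitude=kw.pop("amplitude", 1.0), states=[st])
    return SyntheticTruth(n_slices=kw.pop("n_slices", 20), groups=["G"],
                          proteins={"P": pt}, **kw)


class TestExpectedProfile:
    def test_unit_peak_at_center(self):
        truth = _single_state_truth(center=10, width=1.0, amplitude=1.0)
        prof = expected_profile(truth, "P", "G")
        assert prof[9] == pytest.approx(1.0)
        assert prof.argmax() == 9
        assert prof[8] == pytest.approx(np.exp(-0.5))

    def test_zero_occupancy_gives_zero_profile(self):
        truth = _single_state_truth(occupancy={"G": 0.0})
        np.testing.assert_array_equal(expected_profile(truth, "P", "G"),
                                      np.zeros(20))

    def test_two_states_add_pointwise(self):
        s1 = AssemblyState("a", 5, 1.0, {"G": 1.0})
        s2 = AssemblyState("b", 15, 2.0, {"G": 0.5})
        both = SyntheticTruth(20, ["G"], {
            "P": ProteinTruth("P", 2.0, [s1, s2])})
        only1 = SyntheticTruth(20, ["G"], {"P": ProteinTruth("P", 2.0, [s1])})
        only2 = SyntheticTruth(20, ["G"], {"P": ProteinTruth("P", 2.0, [s2])})
        np.testing.assert_allclose(
            expected_profile(both, "P", "G"),
            expected_profile(only1, "P", "G") + expected_profile(only2, "P", "G"))

    def test_unknown_protein_raises(self):
        with pytest.raises(KeyError):
            expected_profile(_single_state_truth(), "nope", "G")


class TestSimulateExperiment:
    def test_noiseless_equals_expectation(self):
        truth, design = default_study_scenario(noise_cv=0.0, dropout=0.0)
        truth.scale = {}       # unit scale
        m, _ = simulate_experiment(truth, design, seed=5)
        for pid in ("PsbA", "CAND1", "BG01"):
            for s in design.samples:
                np.testing.assert_allclose(
                    m.profile(pid, s),
                    expected_profile(truth, pid, design.group_of[s]))

    def test_same_seed_is_bit_identical(self):
        truth, design = default_study_scenario()
        m1, _ = simulate_experiment(truth, design, seed=12)
        m2, _ = simulate_experiment(truth, design, seed=12)
        np.testing.assert_array_equal(m1.values, m2.values)
        m3, _ = simulate_experiment(truth, design, seed=13)
        assert not np.array_equal(m1.values, m3.values)

    def test_replicate_means_track_expectation(self):
        # CV 0.2, n=3: replicate mean within 3*(CV/sqrt(3))*expected for
        # >= 99% of positive cells, pooled over 20 seeds
        truth, design = default_study_scenario(noise_cv=0.2, dropout=0.0)
        truth.scale = {}
        inside = total = 0
        for seed in range(20):
            m, _ = simulate_experiment(truth, design, seed)
            for pid in ("PsbA", "AtpA", "BG03"):
                exp_wt = expected_profile(truth, pid, "WT")
                reps = m.group_values(pid, "WT")
                mean = reps.mean(axis=1)
                mask = exp_wt > 0
                tol = 3 * (0.2 / np.sqrt(3)) * exp_wt[mask]
                inside += int((np.abs(mean[mask] - exp_wt[mask]) <= tol).sum())
                total += int(mask.sum())
        assert inside / total >= 0.99

    def test_dropout_rate_close_to_nominal(self):
        truth, design = default_study_scenario(noise_cv=0.0, dropout=0.2)
        truth.scale = {}
        m, _ = simulate_experiment(truth, design, seed=7)
        i = m.protein_index("PsbA")
        expected_pos = sum((expected_profile(truth, "PsbA", g) > 0).sum() * 3
                           for g in ("WT", "lpa2"))
        zeroed = expected_pos - np.count_nonzero(m.values[i])
        assert zeroed / expected_pos == pytest.approx(0.2, abs=0.08)

    def test_invalid_noise_parameters_rejected(self):
        with pytest.raises(ValueError):
            _single_state_truth(noise_cv=-0.1)
        with pytest.raises(ValueError):
            _single_state_truth(dropout=1.5)

    def test_annotations_reflect_truth_flags(self):
        truth, design = default_study_scenario()
        _, ann = simulate_experiment(truth, design, seed=1)
        assert ann["DECOY_NOCTP"].has_ctp is False
        assert ann["DECOY_NOCONS"].conserved is False
        assert ann["NPT1"].proteotypic is False
        assert ann["PsbA"].complex == "PSII"


class TestDefaultStudyScenario:
    def test_study_dimensions(self):
        truth, design = default_study_scenario()
        assert truth.n_slices == 36
        assert all(len(design.samples_of(g)) == 3 for g in design.groups)

    def test_noiseless_pipeline_recovers_state_multipliers(self):
        truth, design = default_study_scenario(noise_cv=0.0, dropout=0.0)
        m, ann = simulate_experiment(truth, design, seed=3)
        w = filter_proteotypic(normalize(m).normalized, ann)
        panel = band_ratio_panel(w, study_catalog(), "PSII", "WT", "lpa2",
                                 study_bands())
        for band, mult in TRUTH_MULTIPLIERS.items():
            assert panel[band].median_ratio == pytest.approx(mult, abs=1e-9)

    def test_expected_lane_totals_balanced_across_groups(self):
        truth, _ = default_study_scenario()
        totals = {g: sum(expected_profile(truth, p, g).sum()
                         for p in truth.proteins) for g in truth.groups}
        assert totals["WT"] == pytest.approx(totals["lpa2"], rel=1e-12)

    def test_planted_roles_present(self):
        truth, _ = default_study_scenario()
        assert truth.with_role("planted_comigration") == ["CAND1"]
        assert truth.with_role("planted_band") == ["ENR1", "ENR2", "ENR3"]
        assert len(truth.with_role("decoy")) == 3

    def test_normalization_cancels_planted_scale_factors(self):
        # identical noise draws, different lane loadings -> identical ratios
        truth, design = default_study_scenario()
        rng = np.random.default_rng(2)
        alt = default_study_scenario()[0]
        alt.scale = {s: rng.uniform(0.5, 2.0) for s in design.samples}
        bands, cat = study_bands(), study_catalog()
        meds = []
        for t in (truth, alt):
            m, ann = simulate_experiment(t, design, seed=9)
            w = filter_proteotypic(normalize(m).normalized, ann)
            panel = band_ratio_panel(w, cat, "PSII", "WT", "lpa2", bands)
            meds.append({b: panel[b].median_ratio for b in bands.labels()})
        for b in bands.labels():
            assert meds[0][b] == pytest.approx(meds[1][b], rel=1e-9)


class TestNullScenario:
    def test_welch_null_p_values_match_scipy_and_are_not_anticonservative(self):
        from scipy import stats
        truth, design = null_scenario(300, noise_cv=0.2)
        m, _ = simulate_experiment(truth, design, seed=17)
        ps = []
        for p in m.proteins:
            r = welch_total_abundance_test(m, p, "WT", "lpa2")
            a = m.group_values(p, "WT").sum(axis=0)
            b = m.group_values(p, "lpa2").sum(axis=0)
            assert r.p_value == pytest.approx(
                stats.ttest_ind(a, b, equal_var=False).pvalue, abs=1e-12)
            ps.append(r.p_value)
        assert np.mean(np.array(ps) < 0.05) <= 0.08


class TestScenarioFiles:
    def test_round_trip_through_dict(self):
        spec = {
            "n_slices": 12, "groups": ["WT", "mut"],
            "replicates": {"WT": 2, "mut": 2},
            "noise_cv": 0.1, "dropout": 0.0,
            "proteins": [
                {"protein": "X", "amplitude": 1e5, "has_ctp": True,
                 "states": [{"name": "s", "center": 5, "width": 0.5,
                             "occupancy": {"WT": 1.0, "mut": 0.25}}]},
            ],
        }
        truth, design = truth_from_dict(spec)
        assert truth.n_slices == 12 and design.samples == ["WT_1", "WT_2",
                                                           "mut_1", "mut_2"]
        prof = expected_profile(truth, "X", "mut")
        assert prof[4] == pytest.approx(0.25e5)
        tf = truth_frame(truth)
        assert set(tf.columns) >= {"protein", "state", "occupancy_WT",
                                   "occupancy_mut"}
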