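import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import wavefeat as wf
from wavefeat.datasets import InvalidInputError
from wavefeat.inference import BONFERRONI_ALPHA, correlation_band

from conftest import make_score_table


class TestWelch:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = wf.welch_test(a, a)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.ci_low <= 0 <= res.ci_high

    def test_summary_statistics_from_score_table_row(self):
        # (-1.17, 7.66, 193) vs (4.32, 8.47, 107)
        res = wf.welch_from_summary(-1.17, 7.66, 193, 4.32, 8.47, 107)
        assert res.t == pytest.approx(-5.56, abs=0.01)
        assert res.p < 0.001
        assert res.mean_diff == pytest.approx(-5.49, abs=1e-10)
        assert res.ci_low < res.mean_diff < res.ci_high

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 9)
        r1, r2 = wf.welch_test(a, b), wf.welch_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.ci_low == pytest.approx(-r2.ci_high)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 3, 15)
        res = wf.welch_test(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            wf.welch_test([1.0], [1.0, 2.0])

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(2000, 8))
        b = rng.normal(size=(2000, 10))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestHedgesG:
    def test_published_summary_reproduction(self):
        g = wf.hedges_g(-1.17, 7.66, 193, 4.32, 8.47, 107)
        assert g == pytest.approx(-0.689, abs=0.01)

    def test_unit_difference_hand_computed(self):
        # d = -1, J = 1 - 3/391 = 0.992327 -> g = -0.992
        g = wf.hedges_g(0.0, 1.0, 50, 1.0, 1.0, 50)
        assert g == pytest.approx(-(1 - 3 / 391), abs=1e-12)
        assert g == pytest.approx(-0.992, abs=1e-3)

    def test_equal_means_give_zero(self):
        assert wf.hedges_g(2.0, 1.0, 10, 2.0, 3.0, 12) == 0.0

    def test_degenerate_spread_rejected(self):
        with pytest.raises(wf.UndefinedEffectError):
            wf.hedges_g(0.0, 0.0, 10, 1.0, 0.0, 10)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    def test_invariant_under_common_affine_rescaling(self, scale, shift):
        base = wf.hedges_g(1.0, 2.0, 20, 3.0, 1.5, 15)
        rescaled = wf.hedges_g(scale * 1.0 + shift, scale * 2.0, 20,
                               scale * 3.0 + shift, scale * 1.5, 15)
        assert rescaled == pytest.approx(base, rel=1e-9)

    def test_antisymmetric_under_group_swap(self):
        g1 = wf.hedges_g(1.0, 2.0, 20, 3.0, 1.5, 15)
        g2 = wf.hedges_g(3.0, 1.5, 15, 1.0, 2.0, 20)
        assert g1 == pytest.approx(-g2)


class TestFinalFeatureTable:
    def test_empty_feature_list(self, acceptance_run):
        out = wf.final_feature_table(acceptance_run.score_table, [])
        assert len(out) == 0

    def test_strong_separation_is_significant(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-2, 1, 40), rng.normal(2, 1, 30)])
        table = make_score_table(x, ["symptomatic"] * 40 + ["control"] * 30)
        fid = wf.FeatureId(*table.feature_keys()[0])
        out = wf.final_feature_table(table, [fid], alpha=0.001)
        assert bool(out["significant"].iloc[0])
        assert out["mean_diff"].iloc[0] == pytest.approx(
            out["mean_sym"].iloc[0] - out["mean_con"].iloc[0])
        assert out["ci_low"].iloc[0] < out["mean_diff"].iloc[0] < out["ci_high"].iloc[0]

    def test_participant_unit_aggregates_trials(self, acceptance_run):
        fid = acceptance_run.selection.main_features[0]
        trial = wf.final_feature_table(acceptance_run.score_table, [fid])
        part = wf.final_feature_table(acceptance_run.score_table, [fid],
                                      unit="participant")
        n_parts = acceptance_run.score_table.meta["participant"].nunique()
        assert part["n_sym"].iloc[0] + part["n_con"].iloc[0] == n_parts
        assert trial["n_sym"].iloc[0] + trial["n_con"].iloc[0] \
            == acceptance_run.score_table.n_trials

    def test_ordered_by_variable_then_pc(self, acceptance_run):
        out = wf.final_feature_table(acceptance_run.score_table,
                                     acceptance_run.selection.main_features)
        order = {v: i for i, v in enumerate(wf.VARIABLES)}
        ranks = [(order[v], p) for v, p in zip(out["variable"], out["pc"])]
        assert ranks == sorted(ranks)


class TestAssociatedFeatures:
    def test_band_boundaries(self):
        assert correlation_band(0.49) is None
        assert correlation_band(0.5) == "moderate"
        assert correlation_band(0.699) == "moderate"
        assert correlation_band(0.7) == "strong"
        assert correlation_band(-0.85) == "strong"

    def test_correlated_pair_detected_and_self_excluded(self):
        rng = np.random.default_rng(4)
        n = 300
        base = rng.normal(size=n)
        X = np.column_stack([base, 0.9 * base + 0.4 * rng.normal(size=n),
                             rng.normal(size=n)])
        table = make_score_table(X, ["symptomatic"] * 170 + ["control"] * 130)
        keys = [wf.FeatureId(*k) for k in table.feature_keys()]
        out = wf.associated_features([keys[0]], keys, table)
        assert list(out["associated_feature"]) == [keys[1].label]
        assert out["band"].iloc[0] in ("moderate", "strong")
        assert out["p_corr"].iloc[0] < 0.05

    def test_independent_features_never_associated(self):
        # Monte-Carlo: independent standard-normal score vectors at n=300
        # stay below |rho| = 0.5 in every seeded replicate
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 2))
            table = make_score_table(X, ["symptomatic"] * 150 + ["control"] * 150)
            keys = [wf.FeatureId(*k) for k in table.feature_keys()]
            out = wf.associated_features([keys[0]], keys, table)
            assert len(out) == 0

    def test_significance_flag_tracks_group_t(self):
        rng = np.random.default_rng(5)
        n = 200
        groups = np.array(["symptomatic"] * 120 + ["control"] * 80)
        sep = np.where(groups == "symptomatic", -1.5, 1.5)
        main = sep + rng.normal(0, 1, n)
        assoc = 0.8 * main + 0.3 * rng.normal(size=n)
        table = make_score_table(np.column_stack([main, assoc]), groups)
        keys = [wf.FeatureId(*k) for k in table.feature_keys()]
        out = wf.associated_features([keys[0]], keys, table)
        assert bool(out["significant_associated"].iloc[0])


class TestPointwiseComparison:
    def test_default_alpha_is_bonferroni_over_16(self):
        assert BONFERRONI_ALPHA == pytest.approx(0.05 / 16) == pytest.approx(0.003125)

    def test_planted_offset_flagged_in_window_core(self):
        eff = wf.EffectSpec("theta_HIPFLEX", (20, 50), B=25.0)
        cfg = wf.CohortConfig(n_symptomatic=12, n_control=6,
                              participant_sd={"angle": 0.5, "moment": 0.2},
                              effects=(eff,), seed=6)
        ds, _ = wf.generate_cohort(cfg)
        out = wf.pointwise_group_comparison(ds)
        assert out["theta_HIPFLEX"].mask[30:41].all()
        assert not out["theta_HIPFLEX"].mask[:10].any()
        # unaffected variable stays quiet almost everywhere
        assert out["theta_LUMBARROT"].mask.sum() <= 5

    def test_identical_group_curves_never_significant(self):
        # mirrored participants: each control participant's curves equal one
        # symptomatic participant's, so group means coincide exactly while
        # the between-participant variances stay equal and nonzero
        rng = np.random.default_rng(7)
        curves = rng.normal(size=(3, len(wf.VARIABLES), 101))
        trials = []
        for g, prefix in (("symptomatic", "S"), ("control", "C")):
            for i in range(3):
                for j, v in enumerate(wf.VARIABLES):
                    trials.append(wf.TrialWaveform(
                        f"{prefix}{i}", g, "pivot", "left", 1, v, curves[i, j]))
        ds = wf.WaveformDataset.from_trials(trials)
        out = wf.pointwise_group_comparison(ds)
        for pc in out.values():
            assert not pc.mask.any()


class TestPermutationCalibration:
    def test_null_calibration_on_synthetic_scores(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 30))
        table = make_score_table(X, ["symptomatic"] * 120 + ["control"] * 80)
        keys = [wf.FeatureId(*k) for k in table.feature_keys()]
        out = wf.permutation_calibration(table, keys[:10], keys,
                                         n_permutations=100, seed=9)
        assert out["frac_without_significant_feature"] >= 0.95
        assert 0.02 <= out["mean_screening_retention"] <= 0.10
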