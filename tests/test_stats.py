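"""Group statistics: Welch t, ANOVA, Tukey-Kramer, referencing diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import qsmref as q


class TestWelchT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = q.welch_t(x, x.copy())
        assert res.t == 0.0
        assert res.p == 1.0

    def test_reduces_to_pooled_student_for_equal_n_equal_variance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        y = (y - y.mean()) / y.std(ddof=1) * x.std(ddof=1) + y.mean()  # force S_X = S_Y
        ours = q.welch_t(x, y)
        t_pooled, _ = sps.ttest_ind(x, y, equal_var=True)
        assert ours.t == pytest.approx(t_pooled, rel=1e-12)

    def test_matches_reference_implementation(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(5, 40))
            y = rng.normal(0.3, 2, rng.integers(5, 40))
            ours = q.welch_t(x, y)
            t_ref, p_ref = sps.ttest_ind(x, y, equal_var=False)
            assert ours.t == pytest.approx(t_ref, abs=1e-10)
            assert ours.p == pytest.approx(p_ref, abs=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 200))
    def test_internal_variance_identity(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=12), r.normal(size=9)
        res = q.welch_t(x, y)
        assert res.s2_d == res.s2_x / 12 + res.s2_y / 9  # exact by construction

    def test_degenerate_zero_variance(self):
        same = q.welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert same.t == 0.0 and same.p == 1.0
        apart = q.welch_t([2.0, 2.0, 2.0], [3.0, 3.0])
        assert np.isinf(apart.t) and apart.p == 0.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            q.welch_t([1.0], [1.0, 2.0])


class TestAnova:
    def test_two_groups_f_equals_pooled_t_squared(self, rng):
        x, y = rng.normal(size=15), rng.normal(0.5, 1, size=12)
        f, p = q.anova_oneway([x, y])
        t, p_t = sps.ttest_ind(x, y, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(p_t, rel=1e-10)

    def test_hand_computed_three_group_toy(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]), np.array([6.0, 7.0, 8.0])]
        # manual sums of squares: grand mean 4, SSB = 3*(9+1+16) = 42 on 2 df,
        # SSW = 3*2 = 6 on 6 df, F = 21/1 = 21
        f, p = q.anova_oneway(groups)
        assert f == pytest.approx(21.0, rel=1e-12)
        assert p == pytest.approx(float(sps.f.sf(21.0, 2, 6)), rel=1e-12)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        n_sims, alpha = 2000, 0.05
        groups = [rng.normal(size=(27, n_sims)), rng.normal(size=(19, n_sims)), rng.normal(size=(17, n_sims))]
        _, p = sps.f_oneway(*groups, axis=0)
        # sanity of the simulated null through our wrapper on a subset
        ours = [q.anova_oneway([g[:, i] for g in groups])[1] for i in range(50)]
        assert np.allclose(ours, p[:50], rtol=1e-10)
        rate = float(np.mean(p < alpha))
        assert 0.035 < rate < 0.065  # ~5 sigma binomial band around 0.05

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError):
            q.anova_oneway([np.array([1.0]), np.array([1.0, 2.0])])


class TestTukeyKramer:
    def test_two_groups_q_is_sqrt2_times_pooled_t(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=14)
        out = q.tukey_kramer([x, y], labels=["a", "b"])
        t, _ = sps.ttest_ind(x, y, equal_var=True)
        assert out.loc[0, "q"] == pytest.approx(abs(t) * np.sqrt(2), rel=1e-10)

    def test_matches_reference_implementation(self, rng):
        groups = [rng.normal(0, 1, 12), rng.normal(0.8, 1, 9), rng.normal(0.2, 1, 15)]
        ours = q.tukey_kramer(groups, labels=["g0", "g1", "g2"])
        ref = sps.tukey_hsd(*groups)
        for row in ours.itertuples():
            i = int(row.group1[1])
            j = int(row.group2[1])
            assert row.p == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_only_shifted_group_pairs_significant(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        c = rng.normal(10, 1, 20)
        out = q.tukey_kramer([a, b, c], labels=["a", "b", "c"])
        sig = set(map(tuple, out.loc[out["p"] < 0.05, ["group1", "group2"]].to_numpy()))
        assert sig == {("a", "c"), ("b", "c")}


class TestAgeCorrect:
    def test_zero_slope_leaves_values_nearly_unchanged(self, rng):
        ages = rng.uniform(16, 67, 200)
        vals = rng.normal(0.05, 0.01, 200)
        out = q.age_correct(vals, ages)
        assert np.corrcoef(out, ages)[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(out, vals, atol=0.01)

    def test_injected_slope_is_removed_and_level_kept(self, rng):
        ages = rng.uniform(16, 67, 500)
        noise = rng.normal(0, 0.005, 500)
        vals = 0.05 + 0.001 * (ages - ages.mean()) + noise
        out = q.age_correct(vals, ages)
        assert abs(np.polyfit(ages, out, 1)[0]) < 1e-10  # residual slope
        assert out.mean() == pytest.approx(vals.mean(), rel=1e-12)

    def test_constant_ages_raise(self):
        with pytest.raises(ValueError, match="constant"):
            q.age_correct(np.arange(5.0), np.full(5, 30.0))

    def test_group_specific_mode(self, rng):
        ages = rng.uniform(16, 67, 100)
        groups = np.repeat(["a", "b"], 50)
        vals = np.where(groups == "a", 0.002, -0.001) * ages + rng.normal(0, 0.001, 100)
        out = q.age_correct(vals, ages, groups=groups)
        for g in ("a", "b"):
            sel = groups == g
            assert abs(np.polyfit(ages[sel], out[sel], 1)[0]) < 1e-10


class TestVarianceChange:
    def test_constant_reference_changes_nothing(self, rng):
        x = rng.normal(size=40)
        assert q.variance_change(x, np.full(40, 0.3)) == pytest.approx(0.0, abs=1e-10)

    def test_self_reference_removes_all_variance(self, rng):
        x = rng.normal(size=40)
        assert q.variance_change(x, x) == pytest.approx(-100.0)

    def test_independent_equal_variance_reference_doubles_variance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 200_000)
        r = rng.normal(0, 1, 200_000)
        assert q.variance_change(x, r) == pytest.approx(100.0, abs=2.0)


class TestBienayme:
    def test_self_reference_gives_zero_variance(self, rng):
        x = rng.normal(size=30)
        *_, var_diff = q.bienayme_decomposition(x, x)
        assert var_diff == 0.0

    def test_independent_reference_adds_variances(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 300_000)
        r = rng.normal(0, 2, 300_000)
        var_x, var_r, cov, var_diff = q.bienayme_decomposition(x, r)
        assert abs(cov) < 0.02
        assert var_diff == pytest.approx(var_x + var_r, rel=0.02)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 300), n=st.integers(2, 50))
    def test_identity_holds_for_any_vectors(self, seed, n):
        r = np.random.default_rng(seed)
        x, ref = r.normal(size=n), r.normal(size=n)
        var_x, var_r, cov, var_diff = q.bienayme_decomposition(x, ref)
        assert var_diff == pytest.approx(var_x + var_r - 2 * cov, rel=1e-12, abs=1e-15)


class TestAccuracy:
    def test_truth_is_accurate_against_itself(self, rng):
        v = rng.normal(0.05, 0.01, 500)
        ok, res = q.accuracy_test(v, v.copy())
        assert ok and res.t == 0.0

    def test_self_referenced_roi_is_always_accurate(self, rng):
        recon = rng.normal(0.2, 0.01, 400)  # heavily biased reconstruction
        gt = rng.normal(0.05, 0.01, 400)
        ok, res = q.accuracy_test(recon, gt, recon_ref=recon.mean(), gt_ref=gt.mean())
        assert ok
        assert res.t == 0.0

    def test_biased_reconstruction_is_not_accurate(self, rng):
        gt = rng.normal(0.05, 0.01, 500)
        recon = gt + 0.05
        ok, res = q.accuracy_test(recon, gt)
        assert not ok
        assert abs(res.t) > 10

    def test_truth_in_the_recon_set_is_accurate_everywhere(self, phantom, suite):
        gt_smooth, _ = suite
        _, labels = phantom
        strategies = {
            "none": q.ReferenceStrategy("none"),
            "csf": q.ReferenceStrategy("anatomical", {"roi": "CSF"}),
        }
        copy = q.SusceptibilityVolume(
            gt_smooth.values.copy(), gt_smooth.voxel_size, gt_smooth.brain_mask
        )
        table = q.accuracy_table({"truth": copy}, gt_smooth, labels, strategies)
        assert table.accurate.all()
        assert np.allclose(table.t_values, 0.0)

    def test_referencing_cancels_a_global_bias(self, phantom, suite):
        # recon = gt + constant: inaccurate unreferenced, accurate after any
        # region referencing since the bias difference vanishes
        gt_smooth, _ = suite
        _, labels = phantom
        gt = gt_smooth
        biased = q.SusceptibilityVolume(gt.values + 0.05, gt.voxel_size, gt.brain_mask)
        strategies = {
            "none": q.ReferenceStrategy("none"),
            "csf": q.ReferenceStrategy("anatomical", {"roi": "CSF"}),
            "wholebrain": q.ReferenceStrategy("whole_brain"),
        }
        table = q.accuracy_table({"biased": biased}, gt, labels, strategies)
        by_strat = {s: table.accurate[0, :, i] for i, s in enumerate(table.strategy_names)}
        assert not by_strat["none"].any()
        assert by_strat["csf"].all()
        assert by_strat["wholebrain"].all()

    def test_anatomical_reference_column_marks_its_own_roi_accurate(self, phantom, suite):
        gt_smooth, recons = suite
        _, labels = phantom
        strategies = {
            "none": q.ReferenceStrategy("none"),
            "csf": q.ReferenceStrategy("anatomical", {"roi": "CSF"}),
            "cc": q.ReferenceStrategy("anatomical", {"roi": "corpus_callosum"}),
        }
        table = q.accuracy_table(recons, gt_smooth, labels, strategies)
        csf_idx = table.roi_names.index("CSF")
        cc_idx = table.roi_names.index("corpus_callosum")
        assert table.accurate[:, csf_idx, table.strategy_names.index("csf")].all()
        assert table.accurate[:, cc_idx, table.strategy_names.index("cc")].all()


class TestGroupPipeline:
    def test_posthoc_gating_invariant(self, cohort_table):
        report = q.run_group_pipeline(cohort_table, "csf")
        sig_rois = set(report.anova.loc[report.anova["significant"], "roi"])
        assert set(report.tukey["roi"]) <= sig_rois

    def test_constant_reference_shift_leaves_statistics_unchanged(self, cohort_table):
        # non-degenerate ROIs only: the CSF row referenced to itself is
        # identically zero, where any fp jitter makes F meaningless
        rois = ["putamen", "thalamus", "hippocampus", "caudate"]
        shifted = cohort_table.copy()
        shifted["ref_csf"] = shifted["ref_csf"] + 0.42
        a = q.run_group_pipeline(cohort_table, "csf", rois=rois)
        b = q.run_group_pipeline(shifted, "csf", rois=rois)
        assert np.allclose(a.anova["F"], b.anova["F"], rtol=1e-6)
        assert np.allclose(a.anova["p"], b.anova["p"], rtol=1e-6)
        assert (a.anova["significant"] == b.anova["significant"]).all()

    def test_missing_reference_column_raises(self, cohort_table):
        with pytest.raises(ValueError, match="ref_nosuch"):
            q.run_group_pipeline(cohort_table, "nosuch")

    def test_injected_group_effect_is_detected(self):
        design = q.default_cohort_design(
            effects={("LTLE", "hippocampus"): 0.02, ("RTLE", "hippocampus"): 0.02}, seed=21
        )
        table = q.cohort_to_frame(q.simulate_cohort(design))
        report = q.run_group_pipeline(table, "none")
        row = report.anova.set_index("roi").loc["hippocampus"]
        assert row["significant"]
        assert set(report.tukey.loc[report.tukey["roi"] == "hippocampus", "group1"]) | set(
            report.tukey.loc[report.tukey["roi"] == "hippocampus", "group2"]
        ) == {"HC", "LTLE", "RTLE"}

    def test_correlated_reference_boosts_mean_absolute_t(self):
        # shared subject offset tau^2 = Cov(X, R) > 0: referencing removes it
        res = q.hypothesis_equivalence_sim(
            tau=0.008, sigma=0.005, test_effect=0.004, n_sims=400, seed=3
        )
        assert res["reject_referenced"] >= res["reject_unreferenced"]
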