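import numpy as np
import pytest
from scipy import stats as sps

from detcon.connectivity import ConnectivityTensor, within_subject_reliability
from detcon.groupstats import (
    behavioral_reliability_analysis,
    conjunction,
    dice_overlap,
    effect_size_maps,
    path_ttest,
    threshold_curve,
    threshold_grid,
)

from conftest import copycat_cohort


def tensor_from_r(r, session=0, variant="observed"):
    r = np.asarray(r, dtype=float)
    nan = np.full_like(r, np.nan)
    return ConnectivityTensor(
        r=r, lo=nan, hi=nan, session=session, variant=variant,
        path_index=[(i + 1, 0) for i in range(r.shape[1])],
    )


class TestPathTtest:
    def test_null_paths_give_t_zero_p_one(self):
        st = path_ttest(tensor_from_r(np.zeros((10, 4))))
        np.testing.assert_array_equal(st.t, 0.0)
        np.testing.assert_array_equal(st.p, 1.0)

    def test_noncentrality_matches_closed_form(self):
        # z ~ N(0.09, 0.07) at n = 50: E[t] ~ 0.09 / (0.07 / sqrt(50)) ~ 9.1
        rng = np.random.default_rng(0)
        ts = []
        for _ in range(200):
            z = rng.normal(0.09, 0.07, (50, 3))
            st = path_ttest(tensor_from_r(np.tanh(z)))
            ts.append(st.t)
        assert np.mean(ts) == pytest.approx(9.091, abs=0.5)

    def test_equivalence_with_textbook_oracle(self):
        rng = np.random.default_rng(1)
        r = np.tanh(rng.normal(0.1, 0.3, (20, 15)))
        st = path_ttest(tensor_from_r(r))
        t_ref, p_ref = sps.ttest_1samp(np.arctanh(r), 0.0, axis=0)
        np.testing.assert_allclose(st.t, t_ref, atol=1e-10)
        np.testing.assert_allclose(st.p, p_ref, atol=1e-10)

    def test_zero_variance_sentinel(self):
        st = path_ttest(tensor_from_r(np.full((8, 2), 0.4)))
        assert np.all(np.isinf(st.t)) and np.all(st.t > 0)
        np.testing.assert_array_equal(st.p, 0.0)


class TestConjunction:
    def test_smaller_t_larger_p(self):
        a = path_ttest(tensor_from_r(np.random.default_rng(0).normal(0.3, 0.2, (12, 6))))
        b = path_ttest(tensor_from_r(np.random.default_rng(1).normal(0.1, 0.2, (12, 6))))
        c = conjunction(a, b)
        np.testing.assert_array_equal(c.conj_t, np.minimum(a.t, b.t))
        np.testing.assert_array_equal(c.conj_p, np.maximum(a.p, b.p))

    def test_identical_sessions_are_fixed_point(self):
        a = path_ttest(tensor_from_r(np.random.default_rng(2).normal(0.2, 0.2, (12, 6))))
        c = conjunction(a, a)
        np.testing.assert_array_equal(c.conj_t, a.t)
        np.testing.assert_array_equal(c.conj_p, a.p)

    def test_mismatched_paths_rejected(self):
        a = path_ttest(tensor_from_r(np.zeros((5, 3))))
        b = path_ttest(tensor_from_r(np.zeros((5, 4))))
        with pytest.raises(ValueError, match="mismatch"):
            conjunction(a, b)


class TestDice:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1, 2, 3}, {2, 3}, 0.8),
        ],
    )
    def test_cases(self, a, b, expected):
        assert dice_overlap(a, b) == pytest.approx(expected)

    def test_symmetry_and_self_overlap(self):
        a, b = {1, 5, 9}, {5, 9, 11, 2}
        assert dice_overlap(a, b) == dice_overlap(b, a)
        assert dice_overlap(a, a) == 1.0

    def test_both_empty_is_undefined(self):
        assert np.isnan(dice_overlap(set(), set()))


class TestThresholdCurve:
    def test_grid_endpoints(self):
        grid = threshold_grid()
        assert grid[0] == pytest.approx(0.7411, abs=1e-4)
        assert grid[-1] == pytest.approx(2.9802e-33, rel=1e-4)
        assert np.all(np.diff(grid) < 0)

    def test_bonferroni_point_for_561_paths(self):
        r = np.random.default_rng(0).normal(0.2, 0.2, (10, 561))
        stats = conjunction(path_ttest(tensor_from_r(r)), path_ttest(tensor_from_r(r)))
        curve = threshold_curve(stats)
        assert curve.bonferroni_p == pytest.approx(8.91266e-5, rel=1e-5)

    def test_counts_nonincreasing_and_conjp_consistent(self):
        rng = np.random.default_rng(3)
        a = tensor_from_r(np.tanh(rng.normal(0.15, 0.25, (15, 40))))
        b = tensor_from_r(np.tanh(rng.normal(0.15, 0.25, (15, 40))), session=1)
        stats = conjunction(path_ttest(a), path_ttest(b))
        curve = threshold_curve(stats)
        assert np.all(np.diff(curve.n_conj) <= 0)
        assert np.all(np.diff(curve.n_test) <= 0)
        # max-p conjunction decision == "significant in both sessions"
        for k, thr in enumerate(curve.grid):
            assert curve.n_conj[k] == int((stats.conj_p < thr).sum())
        assert np.all((curve.dice >= 0) & (curve.dice <= 1) | np.isnan(curve.dice))


class TestEffectSizeMaps:
    def test_uniform_medium_effect_fills_and_empties_maps(self):
        r = np.full((10, 20), 0.4)
        maps = effect_size_maps(
            tensor_from_r(r), tensor_from_r(r, 1),
            tensor_from_r(r * 0.5), tensor_from_r(r * 0.5, 1),
        )
        assert maps["conventional_maps"][0.3][0] == set(range(20))
        assert maps["conventional_maps"][0.5][0] == set()

    def test_identical_maps_reach_perfect_dice(self):
        rng = np.random.default_rng(4)
        r = np.tanh(rng.normal(0.4, 0.15, (12, 30)))
        maps = effect_size_maps(
            tensor_from_r(r), tensor_from_r(r, 1),
            tensor_from_r(r), tensor_from_r(r, 1),
        )
        assert maps["best_match"][0.3]["dice"] == pytest.approx(1.0)

    def test_top_fraction_map_size_and_tie_break(self):
        r = np.tile(np.linspace(-0.8, 0.8, 40), (6, 1))
        maps = effect_size_maps(
            tensor_from_r(r), tensor_from_r(r, 1),
            tensor_from_r(r), tensor_from_r(r, 1),
        )
        assert len(maps["top_detectable_paths"]) == 2  # 5% of 40

    def test_sweep_curve_is_unimodal_on_calibrated_cohort(self, small_cohort):
        from detcon.connectivity import (
            detectable_connectivity_tensor,
            observed_connectivity,
        )

        conv = [observed_connectivity(small_cohort, s) for s in (0, 1)]
        det = [detectable_connectivity_tensor(small_cohort, s) for s in (0, 1)]
        maps = effect_size_maps(conv[0], conv[1], det[0], det[1])
        curve = maps["best_match"][0.3]["dice_curve"]
        k = int(np.nanargmax(curve))
        # rises to an interior (or initial-plateau) optimum, then decays
        assert curve[k] >= np.nanmax(curve[k:]) and curve[k] >= curve[-1]
        assert np.nanmax(curve) > 0.3


class TestBehavior:
    def test_copied_sessions_are_perfectly_reliable(self, small_cohort):
        cohort = copycat_cohort(small_cohort)
        rel = within_subject_reliability(cohort)
        out = behavioral_reliability_analysis(cohort, rel)
        assert out["group_curve_r"] == pytest.approx(1.0)
        np.testing.assert_allclose(out["subject_rt_r"], 1.0, atol=1e-12)

    def test_shuffled_subjects_decouple(self, small_cohort):
        import copy

        rel = within_subject_reliability(small_cohort)
        vals = []
        for seed in range(10):
            cohort = copy.copy(small_cohort)
            rng = np.random.default_rng(seed)
            rts = small_cohort.response_times.copy()
            rts[:, :, 1] = rts[rng.permutation(rts.shape[0]), :, 1]
            cohort = type(small_cohort)(
                data=small_cohort.data, config=small_cohort.config,
                nuisance=small_cohort.nuisance, response_times=rts,
            )
            vals.append(behavioral_reliability_analysis(cohort, rel)["coupling_r"])
        assert abs(np.mean(vals)) < 0.25

    def test_missing_rts_rejected(self, small_cohort):
        rel = within_subject_reliability(small_cohort)
        cohort = type(small_cohort)(
            data=small_cohort.data, config=small_cohort.config,
            nuisance=small_cohort.nuisance,
            response_times=small_cohort.response_times,
        )
        cohort.response_times = np.empty((0, 48, 2))
        with pytest.raises(ValueError, match="response times"):
            behavioral_reliability_analysis(cohort, rel)
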