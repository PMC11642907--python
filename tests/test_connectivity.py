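import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detcon.blockboot import BootstrapPlan
from detcon.connectivity import (
    ConnectivityTensor,
    absolute_mean_with_ci,
    connectivity_upper_bound,
    conventional_group_reliability,
    detectable_connectivity,
    detectable_connectivity_tensor,
    fisher_z,
    fisher_z_inverse,
    lower_triangle_paths,
    observed_connectivity,
    within_subject_reliability,
)
from detcon.synthetic import CohortConfig, generate_cohort

from conftest import copycat_cohort

PLAN = BootstrapPlan(n_boot=200, seed=0)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_round_trip(self):
        assert fisher_z_inverse(fisher_z(0.41)) == pytest.approx(0.41, abs=1e-12)

    def test_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestUpperBound:
    @pytest.mark.parametrize(
        "a,b,expected", [(1, 1, 1.0), (0.25, 0.25, 0.25), (-0.3, 0.6, 0.0)]
    )
    def test_cases(self, a, b, expected):
        assert connectivity_upper_bound(a, b) == pytest.approx(expected)


class TestDetectable:
    @pytest.mark.parametrize(
        "obs,ra,rb,expected",
        [
            (0.6, 0.09, 1.0, 0.3),    # capped at sqrt(0.09)
            (-0.6, 0.09, 1.0, -0.3),  # magnitude capped, sign preserved
            (0.8, -0.1, 0.9, 0.0),    # negative reliability zeroes the path
            (0.2, 0.6, 0.9, 0.2),     # below the bound: untouched
        ],
    )
    def test_case_rule(self, obs, ra, rb, expected):
        assert detectable_connectivity(obs, ra, rb) == pytest.approx(expected)

    @given(
        obs=st.floats(-0.999, 0.999),
        ra=st.floats(-0.999, 0.999),
        rb=st.floats(-0.999, 0.999),
    )
    @settings(max_examples=200, deadline=None)
    def test_attenuation_chain_and_idempotence(self, obs, ra, rb):
        det = detectable_connectivity(obs, ra, rb)
        ub = connectivity_upper_bound(ra, rb)
        assert abs(det) <= ub + 1e-12 <= 1 + 1e-12
        assert abs(det) <= abs(obs) + 1e-12
        assert detectable_connectivity(det, ra, rb) == pytest.approx(det, abs=1e-12)


class TestReliability:
    def test_identical_sessions_give_unit_reliability(self, small_cohort):
        table = within_subject_reliability(copycat_cohort(small_cohort))
        np.testing.assert_allclose(table.rho, 1.0, atol=1e-12)

    def test_paper_scale_yields_1700_estimates(self, paper_scale_cohort):
        table = within_subject_reliability(paper_scale_cohort)
        assert table.n_entries == 50 * 34 == 1700
        assert np.isfinite(table.rho).all()

    def test_bootstrap_cis_bracket_point(self, small_cohort):
        table = within_subject_reliability(small_cohort, plan=PLAN)
        ok = (table.lo <= table.rho + 0.05) & (table.rho - 0.05 <= table.hi)
        assert ok.mean() > 0.95


class TestObservedConnectivity:
    def test_34_nodes_give_561_paths(self):
        assert len(lower_triangle_paths(34)) == 561

    def test_duplicated_node_has_unit_path(self, small_cohort):
        cohort = copycat_cohort(small_cohort)
        cohort.data[:, 1] = cohort.data[:, 0]
        t = observed_connectivity(cohort, session=0)
        p = t.path_index.index((1, 0))
        np.testing.assert_allclose(t.r[:, p], 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        cohort = generate_cohort(
            CohortConfig(n_subjects=3, n_nodes=5, n_time=120, n_cycles=4, seed=0)
        )
        t = observed_connectivity(cohort, session=1)
        for s in range(3):
            for p, (i, j) in enumerate(t.path_index):
                expected = np.corrcoef(
                    cohort.data[s, i, :, 1], cohort.data[s, j, :, 1]
                )[0, 1]
                assert t.r[s, p] == pytest.approx(expected, abs=1e-12)

    def test_invalid_session_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="session"):
            observed_connectivity(small_cohort, session=2)


class TestDetectableTensor:
    def test_attenuation_chain_holds_per_path(self, small_cohort):
        rel = within_subject_reliability(small_cohort)
        obs = observed_connectivity(small_cohort, session=0)
        det = detectable_connectivity_tensor(small_cohort, session=0)
        for p, (i, j) in enumerate(det.path_index):
            ub = connectivity_upper_bound(rel.rho[:, i], rel.rho[:, j])
            assert np.all(np.abs(det.r[:, p]) <= ub + 1e-12)
            assert np.all(np.abs(det.r[:, p]) <= np.abs(obs.r[:, p]) + 1e-12)

    def test_joint_bootstrap_cis_are_within_bounds(self, small_cohort):
        det = detectable_connectivity_tensor(small_cohort, session=0, plan=PLAN)
        fin = np.isfinite(det.lo)
        assert fin.all()
        assert np.all(det.lo[fin] <= det.hi[fin])
        assert np.all(det.hi <= 1.0) and np.all(det.lo >= -1.0)


class TestAbsoluteMean:
    @staticmethod
    def tensor(r, lo, hi):
        r = np.atleast_2d(r)
        return ConnectivityTensor(
            r=r,
            lo=np.atleast_2d(lo),
            hi=np.atleast_2d(hi),
            session=0,
            variant="observed",
            path_index=[(i + 1, 0) for i in range(r.shape[1])],
        )

    def test_homogeneous_entries_pass_through(self):
        t = self.tensor([[0.5, 0.5]], [[0.4, 0.4]], [[0.6, 0.6]])
        s = absolute_mean_with_ci(t, n_boot=200)
        assert s.mean_r == pytest.approx(0.5, abs=1e-9)
        assert s.mean_lo == pytest.approx(0.4, abs=1e-9)
        assert s.mean_hi == pytest.approx(0.6, abs=1e-9)
        assert s.pct_negative == 0.0

    def test_robustly_negative_paths_are_absolutized(self):
        t = self.tensor([[0.5, -0.5]], [[0.4, -0.6]], [[0.6, -0.4]])
        s = absolute_mean_with_ci(t, n_boot=200)
        assert s.mean_r == pytest.approx(0.5, abs=1e-9)
        assert s.pct_negative == 0.5
        assert s.mean_lo == pytest.approx(0.4, abs=1e-9)

    def test_uncertainly_negative_paths_are_not(self):
        # CI upper bound >= 0: the sign is not trusted, entry kept as is
        t = self.tensor([[0.5, -0.2]], [[0.4, -0.5]], [[0.6, 0.1]])
        s = absolute_mean_with_ci(t, n_boot=200)
        assert s.pct_negative == 0.0
        assert s.mean_r < 0.2


class TestGroupReliability:
    def test_identical_tensors_give_unit_reliability(self, small_cohort):
        t = observed_connectivity(small_cohort, session=0)
        t2 = ConnectivityTensor(
            r=t.r.copy(), lo=t.lo, hi=t.hi, session=1, variant="observed",
            path_index=t.path_index,
        )
        per_path, mean = conventional_group_reliability(t, t2)
        np.testing.assert_allclose(per_path, 1.0, atol=1e-12)

    def test_subject_permutation_decouples(self):
        rng = np.random.default_rng(0)
        vals = []
        for seed in range(20):
            cohort = generate_cohort(
                CohortConfig(n_subjects=10, n_nodes=6, n_time=240, n_cycles=9, seed=seed)
            )
            a = observed_connectivity(cohort, session=0)
            b = observed_connectivity(cohort, session=1)
            perm = rng.permutation(10)
            b_perm = ConnectivityTensor(
                r=b.r[perm], lo=b.lo[perm], hi=b.hi[perm], session=1,
                variant="observed", path_index=b.path_index,
            )
            vals.append(conventional_group_reliability(a, b_perm)[1])
        assert abs(np.mean(vals)) < 0.1

    def test_path_count_at_paper_scale(self, paper_scale_cohort):
        a = observed_connectivity(paper_scale_cohort, session=0)
        b = observed_connectivity(paper_scale_cohort, session=1)
        per_path, mean = conventional_group_reliability(a, b)
        assert per_path.size == 561
        assert mean > 0.3  # group reliability well above single-subject level

    def test_too_few_subjects_rejected(self, small_cohort):
        t = observed_connectivity(small_cohort, session=0)
        tiny = ConnectivityTensor(
            r=t.r[:2], lo=t.lo[:2], hi=t.hi[:2], session=0, variant="observed",
            path_index=t.path_index,
        )
        with pytest.raises(ValueError, match="3 subjects"):
            conventional_group_reliability(tiny, tiny)


def test_observed_connectivity_recovers_latent_structure():
    """As measurement noise vanishes, per-path observed connectivity
    approaches the correlation implied by the latent factor loadings."""
    cfg = CohortConfig(
        n_subjects=6,
        n_nodes=6,
        n_time=488,
        n_cycles=24,
        zero_gain_fraction=1.0,  # no task signal: connectivity is all latent
        nuisance_leak=0.0,
        noise_sigma=0.05,
        seed=3,
    )
    cohort = generate_cohort(cfg)
    lam = cohort.latent_loadings
    cov = lam @ lam.T + cfg.noise_sigma**2 / (1 - cfg.ar1_phi**2) * np.eye(6)
    d = np.sqrt(np.diag(cov))
    true_r = cov / np.outer(d, d)
    t = observed_connectivity(cohort, session=0)
    for p, (i, j) in enumerate(t.path_index):
        assert np.mean(t.r[:, p]) == pytest.approx(true_r[i, j], abs=0.15)
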