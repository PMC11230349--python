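import numpy as np
import pytest

import connsnr as cs
from connsnr.threshold import SNRProfile


def _fc(mat):
    m = np.asarray(mat, dtype=float)
    return cs.WeightedConnectome(weights=m)


def _profile(taus, snrs, mode="binary"):
    z = np.zeros(len(taus))
    return SNRProfile(taus=np.asarray(taus), snr=np.asarray(snrs), lambda1=z, lambda2=z, mode=mode)


class TestGroupAverage:
    def test_entrywise_mean(self):
        a = _fc([[0, 0.2], [0.2, 0]])
        b = _fc([[0, 0.4], [0.4, 0]])
        ga = cs.group_average(cs.Cohort(connectomes=[a, b]))
        assert ga.weights[0, 1] == pytest.approx(0.3)

    def test_single_member_identity(self):
        a = _fc([[0, 0.2], [0.2, 0]])
        ga = cs.group_average(cs.Cohort(connectomes=[a]))
        assert np.array_equal(ga.weights, a.weights)

    def test_sign_cancellation(self):
        a = _fc([[0, 0.5], [0.5, 0]])
        b = _fc([[0, -0.5], [-0.5, 0]])
        ga = cs.group_average(cs.Cohort(connectomes=[a, b]))
        assert ga.weights[0, 1] == 0.0


class TestThresholdGraph:
    def setup_method(self):
        self.fc = _fc(
            [[0, 0.3, -0.5], [0.3, 0, 0.1], [-0.5, 0.1, 0]]
        )

    def test_magnitude_thresholding(self):
        g = cs.threshold_graph(self.fc, 0.25, mode="binary")
        assert g.n_edges == 2  # |0.3| and |-0.5| survive

    def test_tau_zero_keeps_nonzero_support(self):
        g = cs.threshold_graph(self.fc, 0.0, mode="binary")
        assert g.n_edges == 3

    def test_tau_one_empty(self):
        g = cs.threshold_graph(self.fc, 1.0, mode="binary")
        assert g.n_edges == 0

    def test_weighted_mode_keeps_signed_weights(self):
        g = cs.threshold_graph(self.fc, 0.25, mode="weighted")
        assert g.weights[0, 2] == -0.5
        assert g.weights[1, 2] == 0.0

    def test_positive_only_mode(self):
        g = cs.threshold_graph(self.fc, 0.25, mode="binary", positive_only=True)
        assert g.n_edges == 1  # only +0.3


class TestWeakInterval:
    def test_linear_scan(self):
        prof = _profile([0, 0.05, 0.1, 0.15, 0.2], [0.4, 1.2, 2.5, 1.1, 0.6])
        iv = cs.weak_recoverability_interval(prof)
        assert iv.as_tuple() == (0.05, 0.15)
        assert iv.contiguous

    def test_no_crossing_returns_none(self):
        prof = _profile([0, 0.05], [0.4, 0.9])
        assert cs.weak_recoverability_interval(prof) is None

    def test_non_contiguous_flagged(self):
        prof = _profile([0, 0.05, 0.1], [1.2, 0.5, 1.3])
        iv = cs.weak_recoverability_interval(prof)
        assert iv.as_tuple() == (0.0, 0.1)
        assert not iv.contiguous

    def test_weighted_profile_rejected(self):
        prof = _profile([0, 0.05], [2.0, 2.0], mode="weighted")
        with pytest.raises(ValueError, match="binarized"):
            cs.weak_recoverability_interval(prof)


class TestOptimalThreshold:
    def test_argmax(self):
        tau, deg = cs.optimal_threshold(_profile([0.1, 0.2, 0.3], [0.5, 2.0, 1.0]))
        assert (tau, deg) == (0.2, False)

    def test_tie_breaks_to_smallest(self):
        tau, _ = cs.optimal_threshold(_profile([0.2, 0.25], [2.0, 2.0]))
        assert tau == 0.2

    def test_all_zero_flagged_degenerate(self):
        tau, deg = cs.optimal_threshold(_profile([0.0, 0.5], [0.0, 0.0]))
        assert (tau, deg) == (0.0, True)


class TestTopologyProfile:
    def test_dense_fc_extremes(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.2, 0.9, size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        topo = cs.topology_profile(_fc(m), cs.ThresholdGrid(taus=[0.0, 1.0]))
        assert topo.density[0] == 1.0
        assert topo.components[0] == 1
        assert topo.density[-1] == 0.0
        assert topo.components[-1] == 8

    def test_disconnected_modules_counted(self):
        m = np.zeros((6, 6))
        m[:3, :3] = 0.8
        m[3:, 3:] = 0.8
        np.fill_diagonal(m, 0.0)
        topo = cs.topology_profile(_fc(m), cs.ThresholdGrid(taus=[0.1]))
        assert topo.components[0] == 2

    def test_monotone_density_and_components(self, planted_ga):
        ga, _ = planted_ga
        topo = cs.topology_profile(ga)
        assert np.all(np.diff(topo.density) <= 0)
        assert np.all(np.diff(topo.components) >= 0)


class TestSnrProfile:
    def test_all_small_weights_zero_beyond_bound(self):
        m = np.full((6, 6), 0.15)
        np.fill_diagonal(m, 0.0)
        prof = cs.snr_profile(_fc(m), cs.make_planted_partition(6, 2), mode="binary")
        assert np.all(prof.snr[prof.taus >= 0.2] == 0.0)

    def test_planted_profile_non_monotone_interior_max(self, planted_ga):
        ga, part = planted_ga
        prof = cs.snr_profile(ga, part, mode="weighted")
        i = int(np.argmax(prof.snr))
        assert 0 < i < len(prof.snr) - 1
        assert prof.snr[i] > prof.snr[0] and prof.snr[i] > prof.snr[-1]

    def test_shuffled_partition_profile_lower(self, planted_ga):
        ga, part = planted_ga
        rng = np.random.default_rng(11)
        shuffled = cs.shuffle_partition(part, rng)
        true_prof = cs.snr_profile(ga, part, mode="weighted")
        null_prof = cs.snr_profile(ga, shuffled, mode="weighted")
        keep = true_prof.snr > 0
        assert np.all(null_prof.snr[keep] < true_prof.snr[keep])


class TestReconFC:
    def test_single_subject_ga_equals_subject(self, planted_cohort):
        cohort, part = planted_cohort
        solo = cs.Cohort(connectomes=[cohort.connectomes[0]])
        rep = cs.recon_fc(solo, part)
        (sid,) = rep.tau_opt_individual
        assert rep.tau_opt_individual[sid] == rep.tau_opt_ga

    def test_planted_cohort_all_optima_vetted(self, planted_cohort):
        cohort, part = planted_cohort
        rep = cs.recon_fc(cohort, part)
        assert rep.weak_interval is not None
        assert all(rep.vetting_pass.values())
        grid = set(np.round(rep.profiles[0].taus, 10))
        assert rep.tau_opt_ga in grid
        assert set(np.round(list(rep.tau_opt_individual.values()), 10)) <= grid

    def test_mean_individual_near_group_optimum(self, planted_cohort):
        cohort, part = planted_cohort
        rep = cs.recon_fc(cohort, part)
        assert abs(rep.mean_individual_tau_opt - rep.tau_opt_ga) <= 0.05 + 1e-9

    def test_ga_mask_option_runs(self, planted_cohort):
        cohort, part = planted_cohort
        small = cs.Cohort(connectomes=cohort.connectomes[:3])
        rep = cs.recon_fc(small, part, mask="group_average")
        assert len(rep.tau_opt_individual) == 3

    def test_grid_refinement_stability(self, planted_cohort):
        """tau_opt moves by at most one coarse step under a 5x finer grid."""
        cohort, part = planted_cohort
        ga = cs.group_average(cohort)
        coarse = cs.snr_profile(ga, part, cs.ThresholdGrid.with_step(0.05), mode="weighted")
        fine = cs.snr_profile(ga, part, cs.ThresholdGrid.with_step(0.01), mode="weighted")
        t_coarse, _ = cs.optimal_threshold(coarse)
        t_fine, _ = cs.optimal_threshold(fine)
        assert abs(t_coarse - t_fine) <= 0.05 + 1e-9


class TestRefinementScaling:
    def test_snr_scales_with_parcellation_granularity(self):
        cfg = cs.SimConfig(seed=0)
        base = cs.ConnectomeThreshold.from_simulation(cfg).fit()
        refined = cs.ConnectomeThreshold.from_simulation(cfg, split=2).fit()
        tau_idx = list(np.round(base.report.profiles[1].taus, 10)).index(0.25)
        assert refined.report.profiles[1].snr[tau_idx] > base.report.profiles[1].snr[tau_idx]
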