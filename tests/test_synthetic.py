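import numpy as np
import pytest

from ploopmsm.featurize import carbonyl_angle, ploop_distances, superpose_rmsd
from ploopmsm.synthetic import (GroundTruth, LinkParams, build_toy_ploop,
                                default_truth, emit_features,
                                generate_ensemble, make_crystal_set,
                                make_motor_panel, sample_chain, sample_paths,
                                stationary_distribution, truth_from_thermo)


class TestSampleChain:
    def test_absorbing_identity_stays_put(self):
        path = sample_chain(np.eye(2), n_steps=5, start=0, seed=0)
        assert path.tolist() == [0, 0, 0, 0, 0]

    def test_deterministic_alternation(self):
        T = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert sample_chain(T, 4, start=0, seed=0).tolist() == [0, 1, 0, 1]

    def test_long_run_fraction_matches_closed_form(self):
        # pi = (b, a)/(a+b) for a 2-state chain with rates a=0.1, b=0.2
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        path = sample_chain(T, 10 ** 6, start=0, seed=42)
        assert np.mean(path == 0) == pytest.approx(2 / 3, abs=0.005)

    @pytest.mark.parametrize("T", [np.ones((2, 3)), np.array([[0.5, 0.4], [0.5, 0.5]])])
    def test_invalid_matrix_rejected(self, T):
        with pytest.raises(ValueError):
            sample_chain(T, 10, 0, 0)

    def test_start_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sample_chain(np.eye(2), 10, start=2, seed=0)

    def test_bit_reproducible(self):
        T = default_truth(0).T_true
        a = sample_chain(T, 500, 0, seed=7)
        b = sample_chain(T, 500, 0, seed=7)
        assert np.array_equal(a, b)

    def test_ensemble_frequencies_converge_to_stationary(self, truth):
        """Total-variation distance to the left stationary eigenvector is
        below 0.01 at 10^6 aggregate steps of the default chain."""
        paths = sample_paths(truth, 100, 10 ** 4, seed=3)
        freqs = np.bincount(np.concatenate(paths), minlength=truth.n_states) / 10 ** 6
        tv = 0.5 * np.abs(freqs - truth.pi_true).sum()
        assert tv < 0.01


class TestEmitFeatures:
    def test_zero_noise_limit_reproduces_centers(self, truth):
        tiny = GroundTruth(T_true=truth.T_true, centers=truth.centers,
                           emission_sd=1e-15)
        path = np.array([0, 3, 1])
        X = emit_features(path, tiny, seed=0)
        assert np.allclose(X, truth.centers[path], atol=1e-12)

    def test_sample_mean_obeys_clt_bound(self, truth):
        # norm of the 36-dim mean error: E||err||^2 = d sd^2 / n, so
        # 3 sd sqrt(d/n) is a conservative bound
        n, d = 4000, 36
        wide = GroundTruth(T_true=truth.T_true, centers=truth.centers, emission_sd=1.0)
        X = emit_features(np.zeros(n, dtype=int), wide, seed=5)
        err = np.linalg.norm(X.mean(axis=0) - truth.centers[0])
        assert err < 3 * np.sqrt(d / n)

    def test_nearest_center_labelling_recovers_path(self, truth):
        path = sample_chain(truth.T_true, 2000, 0, seed=9)
        X = emit_features(path, truth, seed=9)
        d = np.linalg.norm(X[:, None] - truth.centers[None], axis=-1)
        recovered = d.argmin(axis=1)
        # centers are ~2 nm apart vs 0.1 nm emission: exact recovery
        assert np.array_equal(recovered, path)

    def test_misclassification_below_two_gaussian_bound(self, truth):
        """Error rate of nearest-center relabelling stays below the analytic
        two-Gaussian bound Phi(-delta / (2 sd)) at the closest center pair."""
        from scipy.stats import norm
        path = sample_chain(truth.T_true, 20000, 0, seed=10)
        X = emit_features(path, truth, seed=10)
        d = np.linalg.norm(X[:, None] - truth.centers[None], axis=-1)
        err = np.mean(d.argmin(axis=1) != path)
        delta = min(np.linalg.norm(truth.centers[i] - truth.centers[j])
                    for i in range(5) for j in range(5) if i != j)
        assert err <= norm.cdf(-delta / (2 * truth.emission_sd)) + 1e-4

    def test_out_of_range_state_rejected(self, truth):
        with pytest.raises(ValueError):
            emit_features(np.array([0, 7]), truth)


class TestToyPloop:
    def test_noiseless_build_is_deterministic(self, toy_a):
        again = build_toy_ploop("A", noise_sd=0.0)
        assert superpose_rmsd(again, toy_a) == pytest.approx(0.0, abs=1e-9)

    def test_carbonyl_flip_exceeds_90_degrees(self, toy_a, toy_b):
        """The A-like and B-like templates differ only by the serine carbonyl
        flip, which shows up as a >90 degree carbonyl-angle change."""
        diff = abs(carbonyl_angle(toy_a, 3, 5) - carbonyl_angle(toy_b, 3, 5))
        assert diff > 90.0

    def test_templates_distinguishable_in_distance_space(self, toy_a, toy_b):
        fa = ploop_distances(toy_a, range(1, 7)).values[0]
        fb = ploop_distances(toy_b, range(1, 7)).values[0]
        assert np.max(np.abs(fa - fb)) > 0.05  # nm

    def test_far_template_beyond_rmsd_threshold(self, toy_a, toy_far):
        assert superpose_rmsd(toy_far, toy_a) > 0.6

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            build_toy_ploop("A", noise_sd=-1.0)

    def test_sidechain_pseudoatoms_optional(self):
        s = build_toy_ploop("A", with_sidechains=True)
        assert s.n_atoms == 30
        assert (s.atom_names == "CB").sum() == 6


class TestCrystalSet:
    def test_extreme_probabilities_give_clean_table(self):
        from ploopmsm.crystal import crystal_contingency, rmsd_partition
        records = make_crystal_set(12, 7, p_bound_within=1.0, p_bound_beyond=0.0, seed=0)
        rmsd_partition(records, build_toy_ploop("A"))
        table = crystal_contingency(records).counts
        assert table.tolist() == [[0, 7], [12, 0]]

    def test_no_beyond_records_all_within(self):
        from ploopmsm.crystal import rmsd_partition
        records = make_crystal_set(10, 0, 0.5, 0.5, seed=1)
        within, beyond = rmsd_partition(records, build_toy_ploop("A"))
        assert len(within) == 10 and not beyond

    def test_matched_generation_reproduces_printed_odds_ratio(self):
        from ploopmsm.crystal import crystal_contingency, fisher_exact, rmsd_partition
        records = make_crystal_set(105, 9, p_bound_within=84 / 105,
                                   p_bound_beyond=1 / 9, seed=2)
        rmsd_partition(records, build_toy_ploop("A"))
        odds, _ = fisher_exact(crystal_contingency(records))
        assert odds == pytest.approx((1 * 21) / (8 * 84))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_crystal_set(-1, 5, 0.5, 0.5)


class TestMotorPanel:
    def test_noiseless_links_are_perfectly_monotone(self):
        from scipy.stats import spearmanr
        lp = LinkParams(duty_noise_sd=0.0, adp_noise_sd=0.0)
        panel = make_motor_panel(6, seed=0, link_params=lp)
        dg = [m.dg_true for m in panel.motors]
        assert spearmanr(dg, [m.duty_obs for m in panel.motors]).statistic == -1.0
        assert spearmanr([m.pab_true for m in panel.motors],
                         [m.adp_obs for m in panel.motors]).statistic == 1.0

    def test_prescribed_probability_ratio_sets_free_energy(self):
        truth = truth_from_thermo(dg_ab=-1.0, p_ab=0.05)
        pi = stationary_distribution(truth.T_true)
        assert -np.log(pi[0] / pi[1]) == pytest.approx(-1.0, abs=1e-9)
        assert pi[0] / pi[1] == pytest.approx(np.e, rel=1e-9)
        assert truth.T_true[0, 1] == pytest.approx(0.05)

    def test_infeasible_prescription_rejected(self):
        with pytest.raises(ValueError):
            truth_from_thermo(dg_ab=-4.0, p_ab=0.9)

    def test_small_panel_rejected(self):
        with pytest.raises(ValueError):
            make_motor_panel(2)

    def test_panel_reproducible(self):
        a = make_motor_panel(4, seed=5)
        b = make_motor_panel(4, seed=5)
        assert all(x.duty_obs == y.duty_obs and x.adp_obs == y.adp_obs
                   and np.array_equal(x.truth.T_true, y.truth.T_true)
                   for x, y in zip(a.motors, b.motors))


def test_generate_ensemble_shapes_and_reproducibility(truth):
    a = generate_ensemble(truth, n_trajectories=3, n_steps=50, seed=2)
    b = generate_ensemble(truth, n_trajectories=3, n_steps=50, seed=2)
    assert a.n_trajectories == 3
    assert all(f.shape == (50, 36) for f in a.features)
    assert all(np.array_equal(x, y) for x, y in zip(a.features, b.features))
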