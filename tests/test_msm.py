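import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploopmsm.cluster import MacroMapping
from ploopmsm.msm import (MicrostateModel, coarse_grain, count_transitions,
                          equilibrium_distribution, equilibrium_macroprob,
                          fit_msm, fit_tmatrix, implied_timescales,
                          implied_timescales_from_T, jackknife, mfpt)
from ploopmsm.synthetic import default_truth, sample_paths

from .oracles import mfpt_monte_carlo, stationary_power_iteration


class TestCountTransitions:
    def test_alternating_sequence(self):
        C = count_transitions([np.array([0, 1, 0, 1])], stride=1)
        assert C.tolist() == [[0, 2], [1, 0]]

    def test_stride_two_with_declared_states(self):
        C = count_transitions([np.array([0, 0, 0])], stride=2, n_states=2)
        assert C.tolist() == [[1, 0], [0, 0]]

    def test_counting_never_crosses_trajectory_boundaries(self):
        C = count_transitions([np.array([0, 1]), np.array([1, 0])], stride=1)
        assert C.tolist() == [[0, 1], [1, 0]]

    def test_all_too_short_rejected(self):
        with pytest.raises(ValueError):
            count_transitions([np.array([0, 1])], stride=5)


class TestFitTmatrix:
    def test_pseudocount_arithmetic(self):
        T, _ = fit_tmatrix(np.array([[0, 2], [1, 0]]))
        assert np.allclose(T, [[1 / 6, 5 / 6], [3 / 4, 1 / 4]])

    def test_symmetric_balanced_counts_give_uniform_pi(self):
        # symmetric counts with equal row sums: T is doubly stochastic
        C = np.array([[2, 5, 1], [5, 0, 3], [1, 3, 4]])
        T, pi = fit_tmatrix(C)
        assert np.allclose(T.sum(axis=0), 1.0)
        assert np.allclose(pi, 1 / 3)

    def test_two_state_closed_form(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert np.allclose(equilibrium_distribution(T), [2 / 3, 1 / 3])

    def test_equilibrium_matches_power_iteration(self, truth):
        """Eigenvector route equals the long-run T^1000 row within 1e-8."""
        pi = equilibrium_distribution(truth.T_true)
        assert np.allclose(pi, stationary_power_iteration(truth.T_true), atol=1e-8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_tmatrix(np.array([[1, -1], [0, 1]]))


class TestImpliedTimescales:
    def test_definition_at_known_eigenvalue(self):
        # 2-state chain engineered so lambda_2 = 1/e at lag 1 ns
        lam = 1 / np.e
        a = (1 - lam) / 2
        T = np.array([[1 - a, a], [a, 1 - a]])
        ts = implied_timescales_from_T(T, lag_ns=1.0)
        assert ts[0] == pytest.approx(1.0, rel=1e-12)

    def test_rank_one_matrix_has_undefined_timescale(self):
        T = np.array([[0.9, 0.1], [0.9, 0.1]])
        assert np.isnan(implied_timescales_from_T(T, 1.0)[0])

    def test_markovian_data_flat_across_lags(self, truth):
        """On exactly Markov chains t_1 is lag-independent (within 10%) and
        matches -tau/ln lambda_2(T_true^stride)."""
        paths = sample_paths(truth, 50, 4000, seed=21)
        table = implied_timescales(paths, [1, 2, 4, 8], truth.frame_interval,
                                   n_states=truth.n_states)
        t1 = np.array([table[s][0] for s in (1, 2, 4, 8)])
        assert np.all(np.isfinite(t1))
        assert t1.max() / t1.min() < 1.10
        for s in (1, 2, 4, 8):
            lam2 = np.sort(np.linalg.eigvals(
                np.linalg.matrix_power(truth.T_true, s)).real)[-2]
            expected = -s * truth.frame_interval / np.log(lam2)
            assert table[s][0] == pytest.approx(expected, rel=0.1)


class TestCoarseGrain:
    def test_identity_mapping_reproduces_micro_model(self, truth):
        paths = sample_paths(truth, 10, 500, seed=2)
        micro = fit_msm(paths, 1, truth.frame_interval)
        mapping = MacroMapping(np.array(list("ABCDE")))
        model = coarse_grain(paths, mapping, 1, truth.frame_interval)
        assert np.allclose(model.T5, micro.T)

    def test_collapse_to_single_state(self):
        mapping = MacroMapping(np.array(["A", "A", "A"]), labels=("A",))
        model = coarse_grain([np.array([0, 1, 2, 1, 0])], mapping, 1)
        assert model.T5.shape == (1, 1)
        assert model.T5[0, 0] == 1.0

    def test_recovered_T5_within_sampling_error(self, truth):
        """Entries of the refit coarse matrix sit within 3 multinomial
        standard errors of the generating T."""
        paths = sample_paths(truth, 40, 2500, seed=8)
        mapping = MacroMapping(np.array(list("ABCDE")))
        model = coarse_grain(paths, mapping, 1, truth.frame_interval)
        counts = model.C5.sum(axis=1)
        for i in range(5):
            se = np.sqrt(truth.T_true[i] * (1 - truth.T_true[i]) / counts[i])
            assert np.all(np.abs(model.T5[i] - truth.T_true[i]) < 3 * se + 1e-3)

    def test_unmapped_microstate_rejected(self):
        mapping = MacroMapping(np.array(["A", "B"]), labels=("A", "B"))
        with pytest.raises(ValueError):
            coarse_grain([np.array([0, 1, 2])], mapping, 1)


class TestEquilibriumMacroprob:
    def test_uniform_micro_over_balanced_mapping(self):
        mapping = MacroMapping(np.array(list("AABBCCDDEE")))
        pi5 = equilibrium_macroprob(np.full(10, 0.1), mapping)
        assert np.allclose(pi5, 0.2)

    def test_all_micro_in_one_state(self):
        mapping = MacroMapping(np.array(["A", "A", "A"]))
        pi5 = equilibrium_macroprob(np.array([0.5, 0.3, 0.2]), mapping)
        assert pi5[0] == pytest.approx(1.0)

    def test_reference_motor_state_probabilities(self):
        """The canonical occupancy split: A 49%, B-D jointly 50%, E 1%."""
        mapping = MacroMapping(np.array(["A", "B", "E"]))
        pi5 = equilibrium_macroprob(np.array([0.49, 0.50, 0.01]), mapping)
        assert np.allclose(pi5[[0, 1, 4]], [0.49, 0.50, 0.01])


class TestMfpt:
    def test_two_state_geometric(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert mfpt(T, 0, 1, lag_ns=1.0) == pytest.approx(10.0)

    def test_source_equals_target(self):
        assert mfpt(np.eye(2), 1, 1, 1.0) == 0.0

    def test_matches_monte_carlo_oracle(self):
        T = np.array([[0.85, 0.10, 0.05],
                      [0.15, 0.80, 0.05],
                      [0.05, 0.10, 0.85]])
        exact = mfpt(T, 0, 2, lag_ns=1.0)
        simulated = mfpt_monte_carlo(T, 0, 2, n_chains=10 ** 5, seed=4)
        assert exact == pytest.approx(simulated, rel=0.02)


class TestJackknife:
    def test_identical_trajectories_zero_error(self):
        trajs = [np.array([1.0, 2.0])] * 5
        est = lambda ts: float(np.mean([t.mean() for t in ts]))
        _, se = jackknife(trajs, est)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula_for_sample_mean(self):
        """On a frozen 4-number set the jackknife SE of the mean equals
        s/sqrt(n) computed directly."""
        values = np.array([2.0, 4.0, 6.0, 12.0])
        trajs = [np.array([v]) for v in values]
        est = lambda ts: float(np.mean([t.mean() for t in ts]))
        theta, se = jackknife(trajs, est)
        assert theta == pytest.approx(values.mean())
        assert se == pytest.approx(values.std(ddof=1) / 2)

    def test_constant_estimator_zero_error(self, rng):
        trajs = [rng.normal(size=5) for _ in range(6)]
        _, se = jackknife(trajs, lambda ts: 42.0)
        assert se == 0.0

    def test_single_trajectory_rejected(self):
        with pytest.raises(ValueError):
            jackknife([np.ones(3)], lambda ts: 0.0)


def test_msm_parameter_recovery_at_default_ensemble_size():
    """100 x 10^4 frames from the default metastable chain: max-abs error of
    T below 0.02 and of pi below 0.01 at every tested lag."""
    truth = default_truth(0)
    paths = sample_paths(truth, 100, 10 ** 4, seed=17)
    for stride in (1, 4):
        model = fit_msm(paths, stride, truth.frame_interval)
        T_expected = np.linalg.matrix_power(truth.T_true, stride)
        assert np.abs(model.T - T_expected).max() < 0.02
        assert np.abs(model.pi - truth.pi_true).max() < 0.01


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.lists(st.integers(0, 3), min_size=2, max_size=30),
                min_size=1, max_size=4))
def test_fitted_models_conserve_probability(seqs):
    """Every fitted T is row-stochastic and every pi sums to one."""
    model = fit_msm([np.array(s) for s in seqs], 1, n_states=4)
    assert np.allclose(model.T.sum(axis=1), 1.0, atol=1e-10)
    assert model.pi.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.allclose(model.pi @ model.T, model.pi, atol=1e-8)
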