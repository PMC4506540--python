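"""Reversible MSM estimation: counting, connectivity, MLE, timescales, CK."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msmbind.msm import (
    CountMatrix,
    TransitionModel,
    ck_test,
    count_transitions,
    estimate_reversible,
    implied_timescales,
    largest_connected_set,
    stationary_distribution,
)
from msmbind.synthetic import sample_markov_chain
from msmbind.trajectories import DiscreteTrajectory


def reversible_loglik_oracle(C: np.ndarray) -> float:
    """Independent constrained-optimization oracle for the reversible MLE.

    Parametrizes the symmetric unnormalized flux as x_ij = exp(y_ij)
    (y symmetric) on the symmetrized sparsity pattern and maximizes the
    likelihood sum_ij c_ij log(x_ij / x_i) with a quasi-Newton method --
    detailed balance and row-stochasticity hold by construction of the
    parametrization, not via the fixed-point update under test.
    """
    from scipy.optimize import minimize

    n = C.shape[0]
    iu = [(i, j) for i in range(n) for j in range(i, n) if C[i, j] + C[j, i] > 0]

    def unpack(y):
        X = np.zeros((n, n))
        for k, (i, j) in enumerate(iu):
            X[i, j] = X[j, i] = np.exp(y[k])
        return X

    def negll(y):
        X = unpack(y)
        xi = X.sum(axis=1)
        mask = C > 0
        return -np.sum(C[mask] * (np.log(X[mask]) - np.log(xi)[np.nonzero(mask)[0]]))

    y0 = np.array([np.log(C[i, j] + C[j, i]) for i, j in iu])
    res = minimize(negll, y0, method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-14})
    return -res.fun


def loglik(C, T):
    mask = C > 0
    return float(np.sum(C[mask] * np.log(T[mask])))


class TestCounting:
    def test_enumerated_pairs_lag_one(self):
        C = count_transitions([DiscreteTrajectory([0, 0, 1, 1, 0])], lag=1)
        np.testing.assert_array_equal(C.counts, [[1, 1], [1, 1]])

    def test_enumerated_pairs_lag_two(self):
        C = count_transitions([DiscreteTrajectory([0, 1, 0, 1])], lag=2)
        np.testing.assert_array_equal(C.counts, [[1, 0], [0, 1]])

    def test_total_counts_sliding_window(self):
        rng = np.random.default_rng(0)
        dts = [DiscreteTrajectory(rng.integers(0, 4, n)) for n in (50, 80, 7)]
        for lag in (1, 3, 6):
            C = count_transitions(dts, lag)
            assert C.total == sum(max(len(d) - lag, 0) for d in dts)

    def test_all_short_rejected(self):
        with pytest.raises(ValueError, match="longer than lag"):
            count_transitions([DiscreteTrajectory([0, 1])], lag=5)


class TestConnectedSet:
    def test_block_diagonal_keeps_larger_block(self):
        C = np.zeros((5, 5))
        C[:3, :3] = 10  # 3-block, more counts
        C[3:, 3:] = 1
        keep, sub = largest_connected_set(CountMatrix(C, lag=1))
        np.testing.assert_array_equal(keep, [0, 1, 2])
        np.testing.assert_array_equal(sub.counts, C[:3, :3])

    def test_fully_connected_identity_restriction(self):
        C = CountMatrix(np.ones((4, 4)), lag=1)
        keep, sub = largest_connected_set(C)
        np.testing.assert_array_equal(keep, np.arange(4))

    def test_absorbing_state_excluded(self):
        # one-way edge 0 -> 2: state 2 absorbs, not strongly connected
        C = np.array([[1.0, 2, 1], [2, 1, 0], [0, 0, 3]])
        with pytest.warns(UserWarning, match="dropped"):
            keep, _ = largest_connected_set(CountMatrix(C, lag=1))
        np.testing.assert_array_equal(keep, [0, 1])

    def test_matches_brute_force_scc(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            C = (rng.random((7, 7)) < 0.25) * rng.integers(1, 5, (7, 7))
            cm = CountMatrix(C.astype(float), lag=1)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                keep, _ = largest_connected_set(cm)
            # brute force: states i,j mutually reachable via matrix powers
            R = np.eye(7, dtype=bool)
            A = C > 0
            for _ in range(7):
                R = R | (R @ A)
            mutual = R & R.T
            sizes = [mutual[i].sum() for i in range(7)]
            def key(s):
                return (len(s), C[np.ix_(sorted(s), sorted(s))].sum())

            best_key = max(
                key(frozenset(np.nonzero(mutual[i])[0])) for i in range(7)
            )
            assert key(frozenset(keep)) == best_key


class TestReversibleMLE:
    def test_symmetric_counts_row_normalize(self):
        C = CountMatrix(np.array([[5.0, 2], [2, 5]]), lag=1)
        m = estimate_reversible(C)
        np.testing.assert_allclose(m.transition_matrix, [[5 / 7, 2 / 7], [2 / 7, 5 / 7]], atol=1e-10)
        np.testing.assert_allclose(m.stationary_distribution, [0.5, 0.5], atol=1e-10)

    def test_two_state_constraint_inactive(self):
        # every 2-state chain is reversible: MLE = row-normalized counts
        C = CountMatrix(np.array([[8.0, 2], [4, 6]]), lag=1)
        m = estimate_reversible(C)
        np.testing.assert_allclose(m.transition_matrix, [[0.8, 0.2], [0.4, 0.6]], atol=1e-9)

    def test_estimator_contract_and_likelihood_vs_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            C = rng.integers(1, 30, (5, 5)).astype(float)
            m = estimate_reversible(CountMatrix(C, lag=1))
            T, pi = m.transition_matrix, m.stationary_distribution
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)
            np.testing.assert_allclose(pi @ T, pi, atol=1e-10)
            flux = pi[:, None] * T
            assert np.max(np.abs(flux - flux.T)) < 1e-8
            assert loglik(C, T) >= reversible_loglik_oracle(C) - 1e-6

    def test_loglikelihood_monotone_over_iterations(self):
        rng = np.random.default_rng(13)
        C = rng.integers(0, 20, (6, 6)).astype(float) + np.eye(6)
        m = estimate_reversible(CountMatrix(C, lag=1), return_loglik_trace=True)
        trace = m.loglik_trace
        assert np.all(np.diff(trace) >= -1e-9)

    def test_recovery_from_sampled_chain(self, ten_state_model):
        truth = ten_state_model
        d = sample_markov_chain(truth, 1_000_000, seed=21)
        C = count_transitions([d], lag=1)
        m = estimate_reversible(C)
        N = C.counts.sum(axis=1)
        T = truth.transition_matrix
        sigma = np.sqrt(T * (1 - T) / N[:, None])
        mask = sigma > 0
        z = np.abs(m.transition_matrix - T)[mask] / sigma[mask]
        assert z.max() < 3.0

    def test_reducible_counts_rejected(self):
        C = np.zeros((3, 3))
        C[:2, :2] = 5
        C[2, 2] = 5
        with pytest.raises(ValueError, match="reducible"):
            estimate_reversible(CountMatrix(C, lag=1))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 8))
    def test_contract_holds_on_random_counts(self, seed, n):
        rng = np.random.default_rng(seed)
        C = rng.integers(1, 50, (n, n)).astype(float)
        m = estimate_reversible(CountMatrix(C, lag=1))
        T, pi = m.transition_matrix, m.stationary_distribution
        assert np.all(T >= 0) and np.all(T <= 1)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)
        flux = pi[:, None] * T
        assert np.max(np.abs(flux - flux.T)) < 1e-8


class TestStationaryDistribution:
    def test_two_state_closed_form(self):
        pi = stationary_distribution(np.array([[0.9, 0.1], [0.2, 0.8]]))
        np.testing.assert_allclose(pi, [2 / 3, 1 / 3], atol=1e-12)

    def test_doubly_stochastic_uniform(self):
        T = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        np.testing.assert_allclose(stationary_distribution(T), np.ones(3) / 3, atol=1e-12)

    def test_agrees_with_power_iteration(self):
        from tests.conftest import random_reversible_matrix

        rng = np.random.default_rng(17)
        for _ in range(5):
            T, pi_true = random_reversible_matrix(6, rng)
            pi = stationary_distribution(T)
            p = np.ones(6) / 6
            for _ in range(10_000):
                p = p @ T
            np.testing.assert_allclose(pi, p, atol=1e-10)
            np.testing.assert_allclose(pi, pi_true, atol=1e-10)

    def test_reducible_rejected(self):
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(np.eye(2))


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # T with a=0.1, b=0.2: lambda_2 = 0.7, t_2 = -1/ln(0.7)
        rng = np.random.default_rng(23)
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        m = TransitionModel(T, np.array([2 / 3, 1 / 3]), lag=1)
        assert m.timescales(1)[0] == pytest.approx(-1 / np.log(0.7), abs=1e-12)

    def test_constant_in_lag_for_markov_data(self, ten_state_model):
        dts = [
            sample_markov_chain(ten_state_model, 200_000, seed=30 + k)
            for k in range(3)
        ]
        tab = implied_timescales(dts, [1, 2, 5, 10], n_timescales=2, n_boot=15, seed=1)
        for k in range(2):
            base, sd0 = tab.timescales[0, k], tab.boot_std[0, k]
            for li in range(1, 4):
                diff = abs(tab.timescales[li, k] - base)
                sd = np.hypot(tab.boot_std[li, k], sd0)
                assert diff <= 2.5 * sd

    def test_no_bootstrap_point_estimates_only(self, ten_state_model):
        d = sample_markov_chain(ten_state_model, 20_000, seed=2)
        tab = implied_timescales([d], [1, 2], n_timescales=2, n_boot=0)
        assert np.all(np.isfinite(tab.timescales))
        assert np.all(np.isnan(tab.boot_mean))


class TestCKTest:
    def test_first_multiple_prediction_equals_estimate(self, ten_state_model):
        d = sample_markov_chain(ten_state_model, 50_000, seed=3)
        sets = [np.where(ten_state_model.conformation_labels == c)[0] for c in range(5)]
        res = ck_test([d], lag=2, multiples=[1, 2, 5], sets=sets)
        np.testing.assert_allclose(res.predicted[:, 0], res.estimated[:, 0], atol=1e-10)

    def test_markov_data_consistent(self, ten_state_model):
        dts = [sample_markov_chain(ten_state_model, 100_000, seed=40 + k) for k in range(2)]
        sets = [np.where(ten_state_model.conformation_labels == c)[0] for c in range(5)]
        res = ck_test(dts, lag=1, multiples=[1, 2, 5, 10], sets=sets, n_boot=10, seed=5)
        sd = np.hypot(res.predicted_std, res.estimated_std)
        z = np.abs(res.predicted - res.estimated) / np.where(sd > 0, sd, np.inf)
        assert (z < 2).mean() >= 0.9

    def test_lumped_non_markovian_data_detected(self):
        # hidden 3-state chain: two slowly-exchanging states lumped into one
        # observed symbol produces non-Markovian statistics
        Th = np.array(
            [[0.98, 0.0, 0.02], [0.0, 0.995, 0.005], [0.02, 0.005, 0.975]]
        )
        Th = Th / Th.sum(axis=1, keepdims=True)
        pi = stationary_distribution(Th)
        hidden = TransitionModel(Th, pi, lag=1)
        d = sample_markov_chain(hidden, 200_000, seed=6)
        lumped = DiscreteTrajectory(np.where(d.states == 2, 1, 0))
        res = ck_test([lumped], lag=1, multiples=[1, 5, 10, 20, 50], sets=[np.array([0]), np.array([1])], n_boot=10, seed=7)
        sd = np.hypot(res.predicted_std, res.estimated_std)
        z = np.abs(res.predicted - res.estimated) / np.where(sd > 0, sd, np.inf)
        assert z.max() > 2.0

    def test_oversized_multiple_dropped(self, ten_state_model):
        d = sample_markov_chain(ten_state_model, 500, seed=8)
        with pytest.warns(UserWarning, match="dropped"):
            res = ck_test([d], lag=10, multiples=[1, 2, 1000], sets=[np.array([0, 1])])
        assert list(res.multiples) == [1, 2]
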