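"""HMM inference: exact oracles, variational fit contracts, run selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdehmm import (HmmConfig, best_of_runs, fit_hmm, forward_backward,
                    free_energy, match_states, viterbi)
from tdehmm.hmm import _backward_impl, _forward_impl, matched_gamma_correlations


def enumerate_posterior(loglik, A, pi):
    """Brute-force posterior marginals, pairwise marginals and evidence by
    summing over every state path."""
    T, K = loglik.shape
    post = np.zeros((T, K))
    xi = np.zeros((T - 1, K, K)) if T > 1 else np.zeros((0, K, K))
    total = 0.0
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(pi[path[0]]) + loglik[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + loglik[t, path[t]]
        p = np.exp(lp)
        total += p
        for t in range(T):
            post[t, path[t]] += p
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += p
        if lp > best_lp:
            best_lp, best_path = lp, path
    return post / total, xi / total, np.log(total), np.asarray(best_path)


def random_case(K, T, seed):
    rng = np.random.default_rng(seed)
    loglik = rng.normal(scale=2.0, size=(T, K))
    A = rng.dirichlet(np.ones(K) * 2, size=K)
    pi = rng.dirichlet(np.ones(K))
    return loglik, A, pi


class TestForwardBackwardOracle:
    @pytest.mark.parametrize("K,T,seed", [
        (2, 3, 0), (2, 8, 1), (3, 5, 2), (3, 8, 3), (2, 1, 4),
    ])
    def test_matches_exhaustive_enumeration(self, K, T, seed):
        loglik, A, pi = random_case(K, T, seed)
        gamma, xi, lz = forward_backward(loglik, A, pi)
        post, xi_ref, lz_ref, _ = enumerate_posterior(loglik, A, pi)
        assert np.abs(gamma - post).max() < 1e-10
        if T > 1:
            assert np.abs(xi - xi_ref).max() < 1e-10
        assert abs(lz - lz_ref) < 1e-10

    def test_single_state(self):
        loglik = np.random.default_rng(0).normal(size=(6, 1))
        gamma, xi, lz = forward_backward(loglik, np.ones((1, 1)),
                                         np.ones(1))
        assert np.all(gamma == 1.0)
        assert lz == pytest.approx(loglik.sum())

    def test_uniform_inputs_give_uniform_posterior(self):
        K, T = 3, 10
        gamma, _, _ = forward_backward(np.zeros((T, K)),
                                       np.full((K, K), 1 / K),
                                       np.full(K, 1 / K))
        assert np.allclose(gamma, 1 / K)

    def test_nan_loglik_names_time_point(self):
        loglik = np.zeros((5, 2))
        loglik[3, 1] = np.nan
        with pytest.raises(ValueError, match="time point 3"):
            forward_backward(loglik, np.full((2, 2), 0.5), np.full(2, 0.5))

    def test_long_chain_no_underflow(self):
        loglik, A, pi = random_case(2, 20_000, 5)
        loglik -= 500.0  # tiny likelihoods everywhere
        gamma, _, lz = forward_backward(loglik, A, pi, return_xi="sum")
        assert np.isfinite(lz)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_xi_sum_equals_full_sum(self):
        loglik, A, pi = random_case(3, 50, 6)
        _, xi_full, _ = forward_backward(loglik, A, pi, return_xi="full")
        _, xi_sum, _ = forward_backward(loglik, A, pi, return_xi="sum")
        assert np.allclose(xi_full.sum(axis=0), xi_sum, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 3), st.integers(2, 12), st.integers(0, 10_000))
    def test_jitted_and_python_kernels_agree(self, K, T, seed):
        loglik, A, pi = random_case(K, T, seed)
        m = loglik.max(axis=1)
        B = np.exp(loglik - m[:, None])
        from tdehmm.hmm import _forward, _backward
        a1, c1 = _forward(B, A, pi)
        a2, c2 = _forward_impl(B, A, pi)
        assert np.allclose(a1, a2, atol=1e-12)
        b1 = _backward(B, A, c1)
        b2 = _backward_impl(B, A, c2)
        assert np.allclose(b1, b2, atol=1e-12)


class TestViterbiOracle:
    @pytest.mark.parametrize("K,T,seed", [(2, 4, 0), (3, 6, 1), (2, 8, 2)])
    def test_matches_enumeration_argmax(self, K, T, seed):
        loglik, A, pi = random_case(K, T, seed)
        path = viterbi(loglik, A, pi)
        _, _, _, best = enumerate_posterior(loglik, A, pi)
        assert np.array_equal(path, best + 1)

    def test_single_state_constant(self):
        path = viterbi(np.zeros((5, 1)), np.ones((1, 1)), np.ones(1))
        assert np.all(path == 1)

    def test_dominant_emissions_pointwise_argmax(self, rng):
        T, K = 30, 3
        loglik = np.full((T, K), -1e4)
        winners = rng.integers(K, size=T)
        loglik[np.arange(T), winners] = 0.0
        path = viterbi(loglik, np.full((K, K), 1 / K), np.full(K, 1 / K))
        assert np.array_equal(path, winners + 1)


class TestFit:
    def test_single_state_recovers_sample_covariance(self, rng):
        Sigma = np.array([[2.0, 0.6], [0.6, 1.0]])
        X = rng.multivariate_normal(np.zeros(2), Sigma, size=4000)
        res = fit_hmm([X], HmmConfig(K=1, n_runs=1, max_iterations=30,
                                     seed=0))
        S_hat = res.state_covariances[0]
        S_emp = X.T @ X / len(X)
        rel = np.linalg.norm(S_hat - S_emp) / np.linalg.norm(S_emp)
        assert rel < 0.05

    def test_three_well_separated_states_recovered(self, rng):
        """Parameter recovery on data drawn from the model itself."""
        from tdehmm import simulate_state_path
        K, d, T = 3, 4, 6000
        A = np.full((K, K), 0.01)
        np.fill_diagonal(A, 0.98)
        covs = [np.diag(s) for s in ([5, 1, 0.2, 1], [0.2, 5, 1, 0.2],
                                     [1, 0.2, 5, 5])]
        path = simulate_state_path(A, T, seed=1)
        X = np.vstack([rng.multivariate_normal(np.zeros(d), covs[k - 1])
                       for k in path])
        res = fit_hmm([X], HmmConfig(K=3, n_runs=2, max_iterations=60,
                                     seed=0))
        post = np.stack([res.gamma[path == k + 1].mean(axis=0)
                         for k in range(K)])
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-post)
        assert post[r, c].mean() >= 0.9

    def test_same_seed_identical_traces(self, rng):
        X = rng.normal(size=(1500, 3))
        cfg = HmmConfig(K=2, n_runs=1, max_iterations=15, seed=42)
        r1 = fit_hmm([X], cfg)
        r2 = fit_hmm([X], cfg)
        assert np.array_equal(r1.free_energy_trace, r2.free_energy_trace)

    def test_simplex_invariants_and_monotone_free_energy(self, small_fit):
        _, res = small_fit
        assert np.allclose(res.gamma.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(res.transition_matrix.sum(axis=1), 1.0,
                           atol=1e-10)
        for S in res.state_covariances:
            assert np.allclose(S, S.T, atol=1e-10)
            assert np.linalg.eigvalsh(S).min() > 0
        tr = res.free_energy_trace
        assert np.all(np.diff(tr) <= 1e-6 * np.abs(tr[:-1]))

    def test_free_energy_recompute_matches_trace(self, rng):
        X = rng.normal(size=(2000, 3))
        X[:1000] *= 2.5
        res = fit_hmm([X], HmmConfig(K=2, n_runs=1, max_iterations=100,
                                     tolerance=1e-8, seed=0))
        assert res.converged
        F = free_energy(res)
        assert F == pytest.approx(res.free_energy,
                                  rel=10 * res.config.tolerance)

    def test_unused_state_costs_only_prior_penalty(self, rng):
        X = rng.multivariate_normal(np.zeros(2), np.eye(2), size=3000)
        f1 = fit_hmm([X], HmmConfig(K=1, n_runs=1, max_iterations=50,
                                    tolerance=1e-8, seed=0)).free_energy
        f2 = fit_hmm([X], HmmConfig(K=2, n_runs=2, max_iterations=50,
                                    tolerance=1e-8, seed=0)).free_energy
        assert abs(f2 - f1) < 5e-3 * abs(f1)

    def test_too_little_data_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_hmm([rng.normal(size=(15, 2))], HmmConfig(K=2, n_runs=1))


class TestBestOfRuns:
    def test_returns_minimum_of_runs(self, rng):
        X = rng.normal(size=(1200, 3))
        X[:600, 0] *= 3
        cfg = HmmConfig(K=2, n_runs=4, max_iterations=20, seed=5)
        res = best_of_runs([X], cfg)
        assert res.all_free_energies.size == 4
        assert res.free_energy == pytest.approx(
            res.all_free_energies.min())

    def test_single_run_equals_fit_hmm(self, rng):
        X = rng.normal(size=(800, 2))
        cfg = HmmConfig(K=2, n_runs=1, max_iterations=10, seed=3)
        res = best_of_runs([X], cfg)
        direct = fit_hmm([X], cfg, run_seed=res.run_seed)
        assert np.array_equal(res.free_energy_trace,
                              direct.free_energy_trace)

    def test_degenerate_data_runs_agree(self, rng):
        """On single-state data every restart converges to an equivalent
        solution (tiny free-energy spread)."""
        X = rng.normal(size=(3000, 2))
        cfg = HmmConfig(K=1, n_runs=3, max_iterations=50, tolerance=1e-8,
                        seed=0)
        res = best_of_runs([X], cfg)
        spread = np.ptp(res.all_free_energies)
        assert spread < 1e-3 * abs(res.free_energy)


class TestMatchStates:
    def test_self_match_is_identity(self, small_fit):
        _, res = small_fit
        assert np.array_equal(match_states(res, res),
                              np.arange(res.K))

    def test_known_relabelling_recovered(self, small_fit):
        import copy
        _, res = small_fit
        perm = np.array([1, 0])
        other = copy.copy(res)
        other.gamma = res.gamma[:, perm]
        other.state_covariances = res.state_covariances[perm]
        assert np.array_equal(match_states(other, res), perm)

    def test_independent_runs_reproducible_states(self, small_cohort):
        """Two runs from different seeds agree on the states (matched
        gamma correlations high) on well-separated data."""
        from tdehmm import EmbeddingConfig, TimeDelayEmbeddedHMM
        _, subjects, _ = small_cohort
        fits = []
        for seed in (10, 20):
            model = TimeDelayEmbeddedHMM(
                subjects, embedding=EmbeddingConfig(n_lags=15),
                config=HmmConfig(K=2, n_runs=1, max_iterations=30,
                                 seed=seed))
            fits.append(model.fit())
        corr = matched_gamma_correlations(fits[0], fits[1])
        assert np.all(corr >= 0.8)
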