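import numpy as np
import pytest

import stickyhmm as sh
from stickyhmm.em import NumericalDegeneracyError, log_emission_matrix

from _oracles import enumerate_paths, poisson_log_emission_oracle
from conftest import random_counts


def small_params(rng, N=3, m=2, dt=0.05):
    Gamma = np.array([[0.9, 0.1], [0.3, 0.7]]) if m == 2 else None
    if Gamma is None:
        G = rng.uniform(0.1, 1.0, size=(m, m))
        Gamma = G / G.sum(axis=1, keepdims=True)
    return sh.HMMParams(
        pi=np.full(m, 1.0 / m),
        Gamma=Gamma,
        Lambda=rng.uniform(0.5, 25.0, size=(N, m)),
        dt=dt,
    )


class TestPoissonLogEmission:
    def test_empty_bin(self, rng):
        params = small_params(rng)
        out = sh.poisson_log_emission(np.zeros(3), params)
        np.testing.assert_allclose(out, -(params.Lambda * params.dt).sum(axis=0))

    def test_unit_mean_single_spike(self):
        # lambda*dt = 1: log pmf(k=1) = log(1 * e^-1) = -1
        params = sh.HMMParams(
            pi=[1.0], Gamma=[[1.0]], Lambda=[[20.0]], dt=0.05
        )
        assert sh.poisson_log_emission(np.array([1]), params) == pytest.approx(-1.0)

    def test_matches_pmf_product_oracle(self, rng):
        params = small_params(rng, N=5, m=3)
        k = rng.poisson(2.0, size=5)
        np.testing.assert_allclose(
            sh.poisson_log_emission(k, params),
            poisson_log_emission_oracle(k, params.Lambda, params.dt),
            atol=1e-12,
        )


class TestForwardBackward:
    def test_single_state_chain(self, rng):
        counts = random_counts(rng, K=2, N=3, T=8)
        params = sh.HMMParams(pi=[1.0], Gamma=[[1.0]],
                              Lambda=rng.uniform(1, 10, (3, 1)), dt=0.05)
        logB = log_emission_matrix(counts, params.Lambda, params.dt)
        fb = sh.forward_backward(logB, params.Gamma, params.pi)
        np.testing.assert_allclose(fb.q, 1.0)
        assert fb.loglik == pytest.approx(logB.sum())

    @pytest.mark.parametrize("m,T", [(2, 4), (3, 6)])
    def test_matches_path_enumeration(self, rng, m, T):
        counts = random_counts(rng, K=1, N=2, T=T)
        params = small_params(rng, N=2, m=m)
        logB = log_emission_matrix(counts, params.Lambda, params.dt)
        fb = sh.forward_backward(logB, params.Gamma, params.pi)
        q, xi, ll = enumerate_paths(logB[0], params.Gamma, params.pi)
        np.testing.assert_allclose(fb.q[0], q, atol=1e-10)
        np.testing.assert_allclose(fb.xi[0], xi, atol=1e-10)
        assert fb.loglik == pytest.approx(ll, abs=1e-10)

    def test_uniform_emissions_follow_chain(self, rng):
        # identical states: posterior determined by the chain alone
        counts = random_counts(rng, K=1, N=2, T=10)
        lam = np.repeat(rng.uniform(2, 10, (2, 1)), 3, axis=1)
        Gamma = np.full((3, 3), 1 / 3)
        logB = log_emission_matrix(counts, lam, 0.05)
        fb = sh.forward_backward(logB, Gamma, np.full(3, 1 / 3))
        np.testing.assert_allclose(fb.q, 1 / 3, atol=1e-12)

    def test_normalisation_and_marginalisation(self, rng):
        counts = random_counts(rng, K=3, N=4, T=15)
        params = small_params(rng, N=4, m=2)
        logB = log_emission_matrix(counts, params.Lambda, params.dt)
        fb = sh.forward_backward(logB, params.Gamma, params.pi)
        np.testing.assert_allclose(fb.q.sum(axis=2), 1.0, atol=1e-8)
        # sum_j xi_ij(t) = q_i(t)
        np.testing.assert_allclose(fb.xi.sum(axis=3), fb.q[:, :-1, :], atol=1e-8)

    def test_agrees_with_hmmlearn(self, rng):
        from hmmlearn.hmm import PoissonHMM as HLPoisson

        counts = random_counts(rng, K=3, N=4, T=20)
        params = small_params(rng, N=4, m=2)
        mine = sh.score(counts, params, pi=params.pi).loglik
        hl = HLPoisson(n_components=2)
        hl.startprob_ = params.pi
        hl.transmat_ = params.Gamma
        hl.lambdas_ = (params.Lambda * params.dt).T
        X = counts.counts.transpose(0, 2, 1).reshape(-1, 4)
        assert mine == pytest.approx(hl.score(X, lengths=[20] * 3), abs=1e-8)

    def test_impossible_emissions_raise(self):
        logB = np.full((1, 3, 2), -np.inf)
        with pytest.raises(NumericalDegeneracyError):
            sh.forward_backward(logB, np.eye(2), np.array([0.5, 0.5]))


class TestMStep:
    def test_hard_assignment_limit(self, rng):
        counts = random_counts(rng, K=1, N=2, T=5)
        K, N, T, m = 1, 2, 5, 2
        q = np.zeros((K, T, m))
        q[:, :, 0] = 1.0
        xi = np.zeros((K, T - 1, m, m))
        xi[:, :, 0, 0] = 1.0
        fb = sh.FBResult(q=q, xi=xi, loglik=0.0, loglik_per_trial=np.zeros(1))
        with pytest.warns(UserWarning):  # state 2 never visited
            new = sh.m_step(fb, counts)
        np.testing.assert_allclose(
            new.Lambda[:, 0], counts.counts[0].mean(axis=1) / counts.dt
        )
        np.testing.assert_allclose(new.Gamma[0], [1.0, 0.0])

    def test_hand_computed_three_bin_instance(self):
        # one trial, 1 neuron, 3 bins, counts (1, 0, 2); hand q and xi
        counts = sh.BinnedCounts(counts=np.array([[[1, 0, 2]]]), dt=0.1)
        q = np.array([[[0.8, 0.2], [0.5, 0.5], [0.3, 0.7]]])
        xi = np.array(
            [[[[0.45, 0.35], [0.05, 0.15]], [[0.2, 0.3], [0.1, 0.4]]]]
        )
        fb = sh.FBResult(q=q, xi=xi, loglik=0.0, loglik_per_trial=np.zeros(1))
        new = sh.m_step(fb, counts)
        # gamma_ij = sum_t xi_ij / sum_{t<T} q_i
        np.testing.assert_allclose(new.Gamma[0], [0.65 / 1.3, 0.65 / 1.3])
        np.testing.assert_allclose(new.Gamma[1], [0.15 / 0.7, 0.55 / 0.7])
        # lambda_i = sum_t q_i k(t) / (dt sum_t q_i)
        np.testing.assert_allclose(
            new.Lambda[0, 0], (0.8 * 1 + 0.5 * 0 + 0.3 * 2) / (0.1 * 1.6)
        )
        np.testing.assert_allclose(
            new.Lambda[0, 1], (0.2 * 1 + 0.5 * 0 + 0.7 * 2) / (0.1 * 1.4)
        )
        np.testing.assert_allclose(new.pi[0], q[0, 0])

    def test_trial_duplication_invariance(self, rng):
        counts = random_counts(rng, K=1, N=3, T=12)
        params = small_params(rng, N=3, m=2)
        logB = log_emission_matrix(counts, params.Lambda, params.dt)
        fb1 = sh.forward_backward(logB, params.Gamma, params.pi)
        one = sh.m_step(fb1, counts)
        dup = sh.BinnedCounts(
            counts=np.concatenate([counts.counts] * 2), dt=counts.dt
        )
        logB2 = log_emission_matrix(dup, params.Lambda, params.dt)
        fb2 = sh.forward_backward(logB2, params.Gamma, params.pi)
        two = sh.m_step(fb2, dup)
        np.testing.assert_allclose(one.Gamma, two.Gamma, atol=1e-12)
        np.testing.assert_allclose(one.Lambda, two.Lambda, atol=1e-10)


class TestTrainPHMM:
    def test_one_state_recovers_mean_rate(self, rng):
        lam_true = 7.0
        counts = sh.BinnedCounts(
            counts=rng.poisson(lam_true * 0.05, size=(5, 2, 200)), dt=0.05
        )
        init = sh.HMMParams(
            pi=[1.0], Gamma=[[1.0]], Lambda=np.full((2, 1), 3.0), dt=0.05
        )
        res = sh.train_phmm(counts, init)
        emp = counts.counts.mean(axis=(0, 2)) / 0.05
        se = np.sqrt(emp / (0.05 * 5 * 200)) + 1e-9
        assert np.all(np.abs(res.params.Lambda[:, 0] - emp) < 2 * se + 1e-6)
        assert res.converged

    def test_fixed_point_converges_immediately(self, rng):
        counts = random_counts(rng, K=2, N=2, T=30)
        init = sh.HMMParams(
            pi=[1.0],
            Gamma=[[1.0]],
            Lambda=(counts.counts.mean(axis=(0, 2)) / counts.dt).reshape(2, 1),
            dt=counts.dt,
        )
        res = sh.train_phmm(counts, init)
        assert res.converged and res.n_iterations <= 2

    def test_monotone_loglik_on_random_suite(self, rng):
        for trial in range(5):
            counts = random_counts(
                rng, K=3, N=4, T=40, lam=rng.uniform(0.3, 2.0)
            )
            init = sh.random_init(counts, 3, seed=trial)
            res = sh.train_phmm(counts, init, maxiter=150)
            traj = res.loglik_trajectory
            rel_drop = np.diff(traj) / np.maximum(np.abs(traj[:-1]), 1.0)
            assert rel_drop.min() > -1e-8

    def test_mmpp_rate_recovery(self):
        spec = sh.random_mmpp_spec(
            3, 10, n_trials=20, trial_duration=14.0, seed=7, diag_range=(0.85, 0.98)
        )
        ds, _ = sh.generate_mmpp(spec)
        counts = sh.bin_spikes(ds, 0.05)
        res = sh.PoissonHMM(counts, 3).fit(n_inits=25, seed=0, maxiter=500)
        matching = sh.match_states(res.params.Lambda, spec.Lambda)
        err = np.mean(
            [
                np.mean(np.abs(res.params.Lambda[:, i] - spec.Lambda[:, j]))
                for i, j, _ in matching
            ]
        )
        assert err < 1.0
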