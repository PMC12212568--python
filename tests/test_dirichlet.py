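import numpy as np
import pytest

import stickyhmm as sh
from stickyhmm.em import log_emission_matrix

from conftest import random_counts


class TestBuildPrior:
    def test_printed_m5_value(self):
        prior = sh.build_prior(5)
        assert prior.A[0, 0] == pytest.approx(4.6)
        assert prior.A[0, 1] == pytest.approx(1.1)

    def test_m2_value(self):
        # a_ii = 1 + 0.9 * 1 * 0.1 / 0.1 = 1.9
        assert sh.build_prior(2).A[0, 0] == pytest.approx(1.9)

    def test_uniform_target_gives_flat_concentrations(self):
        m = 4
        prior = sh.build_prior(m, gamma_bar=1.0 / m, a_bar=1.5)
        np.testing.assert_allclose(prior.A, 1.5)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sh.build_prior(5, gamma_bar=1.0)
        with pytest.raises(ValueError):
            sh.build_prior(1)


class TestPriorMode:
    def test_printed_m5_modes(self):
        mode = sh.prior_mode(sh.build_prior(5))
        assert mode[0, 0] == pytest.approx(0.9)
        assert mode[0, 1] == pytest.approx(0.025)

    def test_symmetric_concentrations_give_uniform_mode(self):
        prior = sh.DirichletPrior(A=np.full((3, 3), 2.0))
        np.testing.assert_allclose(sh.prior_mode(prior), 1 / 3)

    @pytest.mark.parametrize("m", [2, 3, 5, 8])
    @pytest.mark.parametrize("gamma_bar", [0.5, 0.8, 0.9, 0.95])
    def test_mode_roundtrip(self, m, gamma_bar):
        mode = sh.prior_mode(sh.build_prior(m, gamma_bar=gamma_bar, a_bar=1.3))
        np.testing.assert_allclose(np.diag(mode), gamma_bar)
        np.testing.assert_allclose(mode.sum(axis=1), 1.0)

    def test_undefined_mode_raises(self):
        with pytest.raises(ValueError):
            sh.prior_mode(sh.DirichletPrior(A=np.ones((3, 3))))


class TestMAPUpdate:
    def _fb(self, rng, counts, m=2):
        G = rng.uniform(0.2, 1.0, (m, m))
        G /= G.sum(axis=1, keepdims=True)
        lam = rng.uniform(1, 15, (counts.n_neurons, m))
        logB = log_emission_matrix(counts, lam, counts.dt)
        return sh.forward_backward(logB, G, np.full(m, 1 / m))

    def test_uninformative_prior_equals_ml(self, rng):
        counts = random_counts(rng, K=2, N=3, T=12)
        fb = self._fb(rng, counts)
        flat = sh.DirichletPrior(A=np.ones((2, 2)))
        ml = sh.m_step(fb, counts).Gamma
        np.testing.assert_allclose(sh.map_transition_update(fb, flat), ml, atol=1e-14)

    def test_no_data_returns_prior_mode(self):
        prior = sh.build_prior(2)
        fb = sh.FBResult(
            q=np.zeros((1, 1, 2)),
            xi=np.zeros((1, 0, 2, 2)),
            loglik=0.0,
            loglik_per_trial=np.zeros(1),
        )
        np.testing.assert_allclose(
            sh.map_transition_update(fb, prior), sh.prior_mode(prior)
        )

    def test_hand_evaluation(self):
        q = np.array([[[0.8, 0.2], [0.5, 0.5], [0.3, 0.7]]])
        xi = np.array([[[[0.45, 0.35], [0.05, 0.15]], [[0.2, 0.3], [0.1, 0.4]]]])
        fb = sh.FBResult(q=q, xi=xi, loglik=0.0, loglik_per_trial=np.zeros(1))
        prior = sh.build_prior(2)  # a_ii = 1.9, a_ij = 1.1
        got = sh.map_transition_update(fb, prior)
        den0 = 1.3 + 0.9 + 0.1
        np.testing.assert_allclose(got[0], [(0.65 + 0.9) / den0, (0.65 + 0.1) / den0])
        den1 = 0.7 + 0.1 + 0.9
        np.testing.assert_allclose(got[1], [(0.15 + 0.1) / den1, (0.55 + 0.9) / den1])

    def test_map_update_maximises_log_posterior(self, rng):
        # the row-wise MAP formula must beat random stochastic rows on the
        # EM surrogate objective sum_ij (xi_ij + a_ij - 1) log gamma_ij
        counts = random_counts(rng, K=2, N=3, T=20)
        fb = self._fb(rng, counts)
        prior = sh.build_prior(2)
        ghat = sh.map_transition_update(fb, prior)
        xi_sum = fb.xi.sum(axis=(0, 1))
        weights = xi_sum + prior.A - 1.0

        def objective(G):
            return float((weights * np.log(G)).sum())

        best = objective(ghat)
        for _ in range(200):
            G = rng.uniform(0.01, 1.0, (2, 2))
            G /= G.sum(axis=1, keepdims=True)
            assert objective(G) <= best + 1e-12


class TestLogPosterior:
    def test_uninformative_prior_is_identity(self):
        flat = sh.DirichletPrior(A=np.ones((2, 2)))
        G = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert sh.log_posterior(-123.4, G, flat) == pytest.approx(-123.4)

    def test_direct_summation(self):
        prior = sh.build_prior(2)
        G = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = (
            0.9 * np.log(0.9) + 0.1 * np.log(0.1)
            + 0.1 * np.log(0.2) + 0.9 * np.log(0.8)
        )
        assert sh.log_posterior(0.0, G, prior) == pytest.approx(expected)

    def test_zero_transition_with_informative_prior(self):
        prior = sh.build_prior(2)
        G = np.array([[1.0, 0.0], [0.2, 0.8]])
        assert sh.log_posterior(0.0, G, prior) == -np.inf


class TestTrainDPHMM:
    def test_uninformative_prior_reduces_to_phmm(self, rng):
        counts = random_counts(rng, K=2, N=3, T=30)
        init = sh.random_init(counts, 2, seed=4)
        flat = sh.DirichletPrior(A=np.ones((2, 2)))
        a = sh.train_phmm(counts, init, maxiter=80)
        b = sh.train_dphmm(counts, init, flat, maxiter=80)
        n = min(len(a.loglik_trajectory), len(b.loglik_trajectory))
        np.testing.assert_allclose(
            a.loglik_trajectory[:n], b.loglik_trajectory[:n], atol=1e-10
        )

    def test_log_posterior_monotone(self, rng):
        for trial in range(4):
            counts = random_counts(rng, K=2, N=4, T=40, lam=rng.uniform(0.3, 2))
            init = sh.random_init(counts, 3, seed=trial)
            res = sh.train_dphmm(counts, init, sh.build_prior(3), maxiter=120)
            traj = res.loglik_trajectory
            rel_drop = np.diff(traj) / np.maximum(np.abs(traj[:-1]), 1.0)
            assert rel_drop.min() > -1e-8

    def test_recovers_high_diagonals(self):
        spec = sh.random_mmpp_spec(
            3, 10, n_trials=15, trial_duration=10.0, seed=31,
            diag_range=(0.9, 0.98),
        )
        ds, _ = sh.generate_mmpp(spec)
        counts = sh.bin_spikes(ds, 0.05)
        res = sh.DirichletPoissonHMM(counts, 3).fit(n_inits=8, seed=2)
        matching = sh.match_states(res.params.Lambda, spec.Lambda)
        for i, j, _ in matching:
            assert abs(res.params.Gamma[i, i] - spec.Gamma[j, j]) < 0.05
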