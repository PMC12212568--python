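import numpy as np
import pytest

import stickyhmm as sh

from _oracles import hungarian_oracle
from conftest import random_counts


def toy_params(Lambda, Gamma=None, dt=0.05):
    Lambda = np.asarray(Lambda, dtype=float)
    m = Lambda.shape[1]
    if Gamma is None:
        Gamma = np.full((m, m), 0.1 / max(m - 1, 1))
        np.fill_diagonal(Gamma, 0.9)
        Gamma /= Gamma.sum(axis=1, keepdims=True)
    return sh.HMMParams(
        pi=np.full(m, 1 / m), Gamma=Gamma,
        Lambda=np.clip(Lambda, 1e-3, None), dt=dt,
    )


class TestModelDistance:
    def test_hand_instance(self):
        # one trial, one neuron, two bins with counts (2, 0); the decoded
        # state has rate*dt = 1 in both bins: D = (2-1)^2 + (0-1)^2 = 2
        counts = sh.BinnedCounts(counts=np.array([[[2, 0]]]), dt=0.05)
        params = toy_params(np.array([[20.0]]))  # 20 * 0.05 = 1
        assert sh.model_distance(counts, params) == pytest.approx(2.0)

    def test_near_zero_for_silent_data_and_floor_rates(self):
        counts = sh.BinnedCounts(counts=np.zeros((2, 3, 10), dtype=int), dt=0.05)
        params = toy_params(np.full((3, 2), 1e-3))
        assert sh.model_distance(counts, params) == pytest.approx(0.0, abs=1e-6)

    def test_relabeling_invariance(self, rng):
        counts = random_counts(rng, K=2, N=3, T=20)
        params = toy_params(rng.uniform(1, 20, (3, 2)))
        perm = np.array([1, 0])
        assert sh.model_distance(counts, params) == pytest.approx(
            sh.model_distance(counts, params.permute_states(perm))
        )

    def test_additive_over_trials(self, rng):
        counts = random_counts(rng, K=3, N=2, T=15)
        params = toy_params(rng.uniform(1, 15, (2, 2)))
        total = sh.model_distance(counts, params)
        parts = sum(
            sh.model_distance(counts.subset_trials([k]), params) for k in range(3)
        )
        assert total == pytest.approx(parts)


class TestRho:
    def test_identity_is_one(self, rng):
        counts = random_counts(rng, K=2, N=3, T=20)
        params = toy_params(rng.uniform(1, 20, (3, 2)))
        assert sh.rho(counts, params, params).rho == pytest.approx(1.0)

    def test_reciprocal(self, rng):
        counts = random_counts(rng, K=2, N=3, T=20)
        p1 = toy_params(rng.uniform(1, 20, (3, 2)))
        p2 = toy_params(rng.uniform(1, 20, (3, 2)))
        r12 = sh.rho(counts, p1, p2).rho
        r21 = sh.rho(counts, p2, p1).rho
        assert r12 * r21 == pytest.approx(1.0)

    def test_fitted_model_close_to_truth_and_underfit_worse(self):
        spec = sh.random_mmpp_spec(
            4, 20, n_trials=24, trial_duration=10.0, seed=13,
            diag_range=(0.88, 0.97),
        )
        ds, _ = sh.generate_mmpp(spec)
        counts = sh.bin_spikes(ds, 0.05)
        train = counts.subset_trials(range(16))
        valid = counts.subset_trials(range(16, 24))
        true_params = spec.to_params()
        at_true = sh.StickyPoissonHMM(train, 4).fit(n_inits=6, seed=0)
        under = sh.StickyPoissonHMM(train, 2).fit(n_inits=6, seed=0)
        rho_true = sh.rho(valid, at_true.params, true_params).rho
        rho_under = sh.rho(valid, under.params, true_params).rho
        assert rho_true <= 1.05
        assert rho_under > rho_true


class TestMatchStates:
    def test_identity(self, rng):
        lam = rng.uniform(1, 20, (4, 3))
        matching = sh.match_states(lam, lam)
        assert [(i, j) for i, j, _ in matching] == [(0, 0), (1, 1), (2, 2)]
        assert all(d == 0 for _, _, d in matching)

    def test_recovers_permutation(self, rng):
        lam = rng.uniform(1, 20, (5, 4))
        perm = np.array([2, 0, 3, 1])
        matching = sh.match_states(lam[:, perm], lam)
        for i, j, d in matching:
            assert perm[i] == j
            assert d == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("m", [3, 4, 6])
    def test_matches_exhaustive_search(self, rng, m):
        lam1 = rng.uniform(0, 30, (4, m))
        lam2 = rng.uniform(0, 30, (4, m))
        matching = sh.match_states(lam1, lam2)
        total = sum(d for _, _, d in matching)
        diff = lam1[:, :, None] - lam2[:, None, :]
        cost = np.sqrt((diff**2).sum(axis=0))
        _, best = hungarian_oracle(cost)
        assert total == pytest.approx(best)

    def test_unequal_sizes_partial_matching(self, rng):
        lam1 = rng.uniform(1, 20, (3, 4))
        lam2 = rng.uniform(1, 20, (3, 2))
        matching = sh.match_states(lam1, lam2)
        assert len(matching) == 2


class TestShuffledNull:
    def test_single_state_degenerate(self, rng):
        counts = random_counts(rng, K=2, N=2, T=10)
        p = toy_params(rng.uniform(1, 10, (2, 1)), Gamma=np.array([[1.0]]))
        rep = sh.shuffled_rho_null(counts, p, p, n_shuffles=10, seed=0)
        np.testing.assert_allclose(rep.shuffled_rho, rep.rho)

    def test_shuffle_preserves_structure(self, rng):
        # re-implement one shuffle step to assert the invariants it must keep
        counts = random_counts(rng, K=2, N=3, T=15)
        p1 = toy_params(rng.uniform(1, 20, (3, 4)))
        p2 = toy_params(rng.uniform(1, 20, (3, 4)))
        rep = sh.shuffled_rho_null(counts, p1, p2, n_shuffles=5, seed=1)
        assert rep.shuffled_rho.shape == (5,)
        assert 0.0 <= rep.exceedance_probability <= 1.0

    def test_null_narrowly_distributed_around_one_for_matched_model(self):
        # on ground-truth surrogates the decoded-error statistic is dominated
        # by the emission fit, which identity shuffles preserve: the null is
        # narrowly concentrated around 1 and the matched model itself stays
        # within a few percent of the generating model
        spec = sh.random_mmpp_spec(
            3, 15, n_trials=20, trial_duration=10.0, seed=29,
            diag_range=(0.87, 0.96),
        )
        ds, _ = sh.generate_mmpp(spec)
        counts = sh.bin_spikes(ds, 0.05)
        train = counts.subset_trials(range(14))
        valid = counts.subset_trials(range(14, 20))
        fit = sh.StickyPoissonHMM(train, 3).fit(n_inits=6, seed=0)
        rep = sh.shuffled_rho_null(
            valid, fit.params, spec.to_params(), n_shuffles=60, seed=0
        )
        assert rep.rho <= 1.05
        assert abs(rep.shuffled_rho.mean() - 1.0) < 0.05
        assert rep.shuffled_rho.std() < 0.05


class TestRhoLLvAnticorrelation:
    def test_rho_mirrors_validation_likelihood(self):
        # over a range of m, the rho index against the true model and the
        # held-out log-likelihood must rank models oppositely
        spec = sh.random_mmpp_spec(
            3, 15, n_trials=20, trial_duration=10.0, seed=37,
            diag_range=(0.88, 0.96),
        )
        ds, _ = sh.generate_mmpp(spec)
        counts = sh.bin_spikes(ds, 0.05)
        train = counts.subset_trials(range(14))
        valid = counts.subset_trials(range(14, 20))
        true_params = spec.to_params()
        rhos, llvs = [], []
        for m in (1, 2, 3, 4):
            fit = sh.PoissonHMM(train, m).fit(n_inits=5, seed=m)
            rhos.append(sh.rho(valid, fit.params, true_params).rho)
            llvs.append(sh.score(valid, fit.params).loglik)
        r = np.corrcoef(rhos, llvs)[0, 1]
        assert r < -0.9
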