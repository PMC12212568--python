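"""Baum-Welch core for Poisson-family HMMs on multi-trial spike counts.

Observations are spike-count vectors ``k(t)`` over ``N`` neurons in bins of
width ``dt``.  In hidden state ``i`` neuron ``n`` fires Poisson with mean
``lambda_ni * dt`` and neurons are conditionally independent given the
state, so the per-bin log emission is

    log e_i(k) = sum_n [ k_n log(lambda_ni dt) - lambda_ni dt - log k_n! ].

The E-step runs the scaled forward-backward recursions batched over trials
(all trials share the same bin count), producing the posteriors ``q_i(t)``,
the pairwise posteriors ``xi_ij(t)`` and the exact log-likelihood.  The
M-step re-estimates ``pi`` per trial from ``q_i(1)`` and ``Gamma``/``Lambda``
from numerators and denominators pooled over trials.  Reported
log-likelihoods always include the ``log k!`` constants so values are
comparable across models and usable in BIC/AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import BinnedCounts
from .params import RATE_FLOOR, HMMParams

__all__ = [
    "FBResult",
    "TrainResult",
    "NumericalDegeneracyError",
    "poisson_log_emission",
    "log_emission_matrix",
    "forward_backward",
    "m_step",
    "train_phmm",
]


class NumericalDegeneracyError(FloatingPointError):
    """All state paths have zero probability (impossible emissions)."""


@dataclass
class FBResult:
    """E-step output: posteriors, pairwise posteriors and log-likelihood.

    ``q`` has shape (trials, bins, m); ``xi`` has shape
    (trials, bins-1, m, m) with ``xi[k, t]`` the joint posterior of states
    at bins t and t+1.  ``loglik`` is the total over trials; the per-trial
    decomposition is kept for cross-validation.
    """

    q: np.ndarray
    xi: np.ndarray
    loglik: float
    loglik_per_trial: np.ndarray


@dataclass
class TrainResult:
    """Outcome of one EM run from one initial guess."""

    params: HMMParams
    loglik_trajectory: np.ndarray
    converged: bool
    n_iterations: int
    min_self_transition: float
    n_resets: int = 0
    #: final complete-data log-likelihood (always includes log k! terms);
    #: for MAP training this is the log-likelihood, while
    #: ``objective_trajectory`` (== loglik_trajectory) tracks the monitored
    #: objective (log-posterior for the Dirichlet model).
    loglik: float = np.nan

    def __post_init__(self) -> None:
        self.loglik_trajectory = np.asarray(self.loglik_trajectory, dtype=float)
        if np.isnan(self.loglik) and self.loglik_trajectory.size:
            self.loglik = float(self.loglik_trajectory[-1])


def poisson_log_emission(counts_bin: np.ndarray, params: HMMParams) -> np.ndarray:
    """Log emission probabilities of one spike-count vector under each state."""
    k = np.asarray(counts_bin, dtype=float)
    if np.any(k < 0):
        raise ValueError("spike counts must be non-negative")
    lam_dt = params.Lambda * params.dt  # (N, m)
    return k @ np.log(lam_dt) - lam_dt.sum(axis=0) - gammaln(k + 1).sum()


def log_emission_matrix(counts: BinnedCounts, Lambda: np.ndarray, dt: float) -> np.ndarray:
    """Per-bin log emissions for all trials: shape (trials, bins, m)."""
    lam_dt = Lambda * dt
    log_lam = np.log(lam_dt)
    # counts: (K, N, T); einsum gives (K, T, m)
    out = np.einsum("knt,nm->ktm", counts.counts, log_lam, optimize=True)
    out -= lam_dt.sum(axis=0)
    out -= gammaln(counts.counts + 1.0).sum(axis=1)[..., None]
    return out


def forward_backward(log_emissions: np.ndarray, Gamma: np.ndarray, pi: np.ndarray) -> FBResult:
    """Scaled forward-backward over a batch of equal-length trials.

    ``log_emissions`` has shape (trials, bins, m); ``pi`` is (m,) or
    (trials, m).  Forward variables are normalised per bin, with the log
    scale factors accumulated, so the returned log-likelihood is exact.
    """
    K, T, m = log_emissions.shape
    pi = np.atleast_2d(pi)
    if pi.shape[0] == 1:
        pi = np.broadcast_to(pi, (K, m))
    # stabilise emissions per (trial, bin)
    cmax = log_emissions.max(axis=2, keepdims=True)  # (K, T, 1)
    if not np.all(np.isfinite(cmax)):
        raise NumericalDegeneracyError("all emissions impossible in some bin")
    b = np.exp(log_emissions - cmax)  # in (0, 1]

    alpha = np.empty((K, T, m))
    scale = np.empty((K, T))
    a = pi * b[:, 0]
    s = a.sum(axis=1)
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise NumericalDegeneracyError("zero total probability at bin 0")
    alpha[:, 0] = a / s[:, None]
    scale[:, 0] = s
    for t in range(1, T):
        a = (alpha[:, t - 1] @ Gamma) * b[:, t]
        s = a.sum(axis=1)
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise NumericalDegeneracyError(f"zero total probability at bin {t}")
        alpha[:, t] = a / s[:, None]
        scale[:, t] = s

    beta = np.empty((K, T, m))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = (b[:, t + 1] * beta[:, t + 1]) @ Gamma.T / scale[:, t + 1, None]

    q = alpha * beta
    q /= q.sum(axis=2, keepdims=True)  # exact normalisation against round-off

    # xi[k, t, i, j] = alpha_t(i) Gamma_ij b_{t+1}(j) beta_{t+1}(j) / s_{t+1}
    right = b[:, 1:] * beta[:, 1:] / scale[:, 1:, None]  # (K, T-1, m)
    xi = alpha[:, :-1, :, None] * Gamma[None, None] * right[:, :, None, :]

    loglik_per_trial = np.log(scale).sum(axis=1) + cmax[:, :, 0].sum(axis=1)
    return FBResult(
        q=q,
        xi=xi,
        loglik=float(loglik_per_trial.sum()),
        loglik_per_trial=loglik_per_trial,
    )


def m_step(
    fb: FBResult,
    counts: BinnedCounts,
    prior_A: np.ndarray | None = None,
) -> HMMParams:
    """Re-estimate (pi, Gamma, Lambda) from E-step posteriors.

    ``pi`` is re-estimated per trial as ``q_i(1)``; Gamma and Lambda pool
    numerators and denominators over all trials.  When ``prior_A`` (a matrix
    of Dirichlet concentration parameters) is given, the transition update
    is the MAP formula with ``a_ij - 1`` pseudo-counts; with all
    ``a_ij = 1`` it reduces exactly to maximum likelihood.  Rates are
    clamped to the floor of 0.001 spikes/s.  States with vanishing expected
    occupancy keep a uniform transition row and floor rates.
    """
    q, xi = fb.q, fb.xi
    K, T, m = q.shape
    dt = counts.dt

    pi = q[:, 0, :].copy()

    xi_sum = xi.sum(axis=(0, 1))  # (m, m)
    q_trans = q[:, :-1, :].sum(axis=(0, 1))  # (m,)
    if prior_A is not None:
        A1 = np.asarray(prior_A, dtype=float) - 1.0
        num = xi_sum + A1
        den = q_trans + A1.sum(axis=1)
    else:
        num = xi_sum
        den = q_trans
    Gamma = np.empty((m, m))
    dead = den <= 1e-12
    Gamma[~dead] = num[~dead] / den[~dead, None]
    if np.any(dead):
        import warnings

        warnings.warn(
            f"state(s) {np.flatnonzero(dead).tolist()} never visited; "
            "transition rows set uniform, rates set to floor",
            stacklevel=2,
        )
        Gamma[dead] = 1.0 / m
    Gamma /= Gamma.sum(axis=1, keepdims=True)

    q_all = q.sum(axis=(0, 1))  # (m,)
    num_lam = np.einsum("knt,ktm->nm", counts.counts, q, optimize=True)
    Lambda = np.empty((counts.n_neurons, m))
    alive = q_all > 1e-12
    Lambda[:, alive] = num_lam[:, alive] / (q_all[alive] * dt)
    Lambda[:, ~alive] = RATE_FLOOR
    np.clip(Lambda, RATE_FLOOR, None, out=Lambda)

    return HMMParams(pi=pi, Gamma=Gamma, Lambda=Lambda, dt=dt)


def _param_delta(old: HMMParams, new: HMMParams) -> float:
    """Largest parameter change: Gamma entries and expected counts Lambda*dt."""
    dg = np.max(np.abs(new.Gamma - old.Gamma))
    dl = np.max(np.abs(new.Lambda - old.Lambda)) * old.dt
    return max(dg, dl)


def _run_em(
    counts: BinnedCounts,
    init: HMMParams,
    *,
    maxiter: int = 1000,
    tol: tuple = (1e-6, 1e-6),
    prior_A: np.ndarray | None = None,
    log_prior_fn=None,
    sticky=None,
    fixed_pi: bool = False,
) -> TrainResult:
    """Shared EM loop for PHMM / DPHMM / sPHMM.

    ``log_prior_fn(Gamma)`` (if given) is added to the log-likelihood to
    form the monitored objective; ``prior_A`` switches the transition
    update to MAP.  ``sticky`` is a mapping with keys theta, epsilon and an
    ``rng`` used for the rate-vector shuffle at resets (see module
    ``sticky``).
    """
    tol1, tol2 = tol
    params = init
    trajectory = []
    converged = False
    n_resets = 0
    last_loglik = np.nan

    theta = sticky["theta"] if sticky else None
    snapshot = None
    if sticky:
        if params.min_self_transition < theta - 1e-9:
            raise ValueError(
                "sticky training requires an initial guess with all "
                f"self-transitions >= theta={theta}"
            )
        snapshot = (params.Gamma.copy(), params.Lambda.copy())

    prev_obj = -np.inf
    it = 0
    while it < maxiter:
        it += 1
        logB = log_emission_matrix(counts, params.Lambda, params.dt)
        fb = forward_backward(logB, params.Gamma, params.pi)
        last_loglik = fb.loglik
        obj = fb.loglik
        if log_prior_fn is not None:
            obj += log_prior_fn(params.Gamma)
        trajectory.append(obj)

        new = m_step(fb, counts, prior_A=prior_A)
        if fixed_pi:
            new = HMMParams(pi=params.pi, Gamma=new.Gamma, Lambda=new.Lambda, dt=new.dt)

        reset_fired = False
        if sticky:
            d_old = np.diag(params.Gamma)
            d_new = np.diag(new.Gamma)
            offending = (np.abs(d_new - d_old) < sticky["epsilon"]) & (d_new < theta)
            if np.any(offending):
                # restore the last snapshot where all gamma_ii >= theta and
                # shuffle the firing-rate vectors across states
                g_star, l_star = snapshot
                perm = sticky["rng"].permutation(params.m)
                new = HMMParams(
                    pi=new.pi, Gamma=g_star.copy(), Lambda=l_star[:, perm].copy(), dt=new.dt
                )
                n_resets += 1
                reset_fired = True
                prev_obj = -np.inf  # objective will jump; restart convergence test
            elif np.all(d_new >= theta):
                snapshot = (new.Gamma.copy(), new.Lambda.copy())

        if not reset_fired:
            delta = _param_delta(params, new)
            rel = abs(obj - prev_obj) / max(abs(prev_obj), 1.0)
            if np.isfinite(prev_obj) and rel < tol1 and delta < tol2:
                params = new
                converged = True
                break
        prev_obj = obj
        params = new

    if sticky and converged and params.min_self_transition < theta:
        converged = False  # defensive: never report a converged sub-threshold fit

    return TrainResult(
        params=params,
        loglik_trajectory=np.array(trajectory),
        converged=converged,
        n_iterations=it,
        min_self_transition=params.min_self_transition,
        n_resets=n_resets,
        loglik=float(last_loglik),
    )


def train_phmm(
    counts: BinnedCounts,
    init: HMMParams,
    maxiter: int = 1000,
    tol: tuple = (1e-6, 1e-6),
    fixed_pi: bool = False,
) -> TrainResult:
    """Maximum-likelihood Baum-Welch training of the Poisson HMM.

    Alternates the scaled forward-backward E-step and the pooled M-step
    until the relative log-likelihood change drops below ``tol[0]`` and the
    largest parameter change below ``tol[1]``, or ``maxiter`` is reached.
    """
    if init.m < 1:
        raise ValueError("need at least one state")
    return _run_em(counts, init, maxiter=maxiter, tol=tol, fixed_pi=fixed_pi)


def score(counts: BinnedCounts, params: HMMParams, pi: np.ndarray | None = None) -> FBResult:
    """Evaluate posteriors and log-likelihood of data under fixed parameters.

    By default the initial distribution is taken from ``params`` when its
    trial dimension matches, and falls back to the stationary distribution
    of Gamma otherwise (the standard choice for held-out trials).
    """
    from .decode import stationary_distribution

    if pi is None:
        if params.pi.ndim == 2 and params.pi.shape[0] == counts.n_trials:
            pi = params.pi
        else:
            pi = stationary_distribution(params.Gamma)
    logB = log_emission_matrix(counts, params.Lambda, params.dt)
    return forward_backward(logB, params.Gamma, pi)
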