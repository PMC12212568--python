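"""Categorical (Multinoulli) HMM benchmark on one-spiking-neuron symbols.

At very short bin widths (default 5 ms) each bin is summarised by one of
N+1 symbols: which neuron fired (symbols 1..N), or silence (symbol N+1).
The emission law of state i is a categorical distribution e_i(n).  Under a
Poisson spike model with rate lambda_ni the per-bin spike probability is
p = 1 - exp(-lambda_ni dt), so fitted emission probabilities convert back
to firing rates via lambda = -log(1 - e) / dt.

The model breaks down when several neurons fire in the same bin; the
probability of such a collision among N conditionally independent Poisson
neurons is 1 - (1-p)^N - N p (1-p)^(N-1), which is why bins longer than
~10 ms are unusable for realistic ensembles.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import SymbolSequence
from .em import NumericalDegeneracyError, TrainResult, forward_backward
from .params import MHMMParams, HMMParams

__all__ = [
    "train_mhmm",
    "rates_from_emissions",
    "multi_spike_probability",
    "mhmm_log_emission_matrix",
]


def mhmm_log_emission_matrix(symbols: SymbolSequence, E: np.ndarray) -> np.ndarray:
    """Per-bin log emissions (trials, bins, m) for a categorical emission row."""
    with np.errstate(divide="ignore"):
        logE = np.log(E)
    return logE[:, symbols.symbols - 1].transpose(1, 2, 0)


def train_mhmm(
    symbols: SymbolSequence,
    init: MHMMParams,
    maxiter: int = 1000,
    tol: tuple = (1e-6, 1e-6, 1e-6),
    fixed_pi: bool = False,
) -> TrainResult:
    """Baum-Welch for the categorical HMM, pooled over trials.

    The emission update is the expected fraction of bins with symbol n
    while in state i; the transition update is the usual ratio of pooled
    pairwise posteriors to occupancies.  Convergence requires the relative
    log-likelihood change below ``tol[0]`` and the largest change of the
    transition and emission matrices below ``tol[1]`` and ``tol[2]``.
    """
    tol1, tol2, tol3 = tol
    if symbols.dt > 0.01:
        warnings.warn(
            "bin width above 10 ms: the categorical spike model is unreliable",
            stacklevel=2,
        )
    params = init
    m, S = init.E.shape
    K, T = symbols.symbols.shape
    # one-hot (K, T, S) used by the emission update
    onehot = np.eye(S)[symbols.symbols - 1]

    trajectory = []
    converged = False
    prev_ll = -np.inf
    it = 0
    while it < maxiter:
        it += 1
        logB = mhmm_log_emission_matrix(symbols, params.E)
        fb = forward_backward(logB, params.Gamma, params.pi)
        trajectory.append(fb.loglik)

        pi = fb.q[:, 0, :].copy() if not fixed_pi else params.pi
        num = fb.xi.sum(axis=(0, 1))
        den = fb.q[:, :-1, :].sum(axis=(0, 1))
        Gamma = np.where(den[:, None] > 1e-12, num / den[:, None], 1.0 / m)
        Gamma /= Gamma.sum(axis=1, keepdims=True)

        occ = fb.q.sum(axis=(0, 1))  # (m,)
        num_e = np.einsum("ktm,kts->ms", fb.q, onehot, optimize=True)
        E = np.where(occ[:, None] > 1e-12, num_e / occ[:, None], 1.0 / S)
        E /= E.sum(axis=1, keepdims=True)

        dG = np.max(np.abs(Gamma - params.Gamma))
        dE = np.max(np.abs(E - params.E))
        rel = abs(fb.loglik - prev_ll) / max(abs(prev_ll), 1.0)
        params = MHMMParams(pi=pi, Gamma=Gamma, E=E, dt=params.dt)
        if np.isfinite(prev_ll) and rel < tol1 and dG < tol2 and dE < tol3:
            converged = True
            break
        prev_ll = fb.loglik

    return TrainResult(
        params=params,
        loglik_trajectory=np.array(trajectory),
        converged=converged,
        n_iterations=it,
        min_self_transition=params.min_self_transition,
    )


def rates_from_emissions(params: MHMMParams) -> np.ndarray:
    """Firing rates implied by fitted emissions: lambda = -log(1 - e)/dt.

    Returns an (N, m) matrix over the neuron symbols (silence excluded).
    """
    e = params.E[:, : params.n_neurons]  # (m, N)
    if np.any(e >= 1.0):
        raise FloatingPointError("emission probability 1 implies infinite rate")
    return (-np.log1p(-e) / params.dt).T


def multi_spike_probability(n_neurons: int, rate: float, dt: float) -> float:
    """Probability that two or more neurons spike in the same bin.

    With per-neuron spike probability p = 1 - exp(-rate*dt) and N
    conditionally independent neurons, this is
    1 - (1-p)^N - N p (1-p)^(N-1).  For N=100 neurons at 5 spikes/s and
    2 ms bins it is ~0.26 -- the collision load that rules out the
    categorical code for large ensembles.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = -np.expm1(-rate * dt)
    N = n_neurons
    return float(1.0 - (1 - p) ** N - N * p * (1 - p) ** (N - 1))


def score_mhmm(symbols: SymbolSequence, params: MHMMParams, pi=None):
    """Posteriors/log-likelihood of symbols under fixed categorical params."""
    from .decode import stationary_distribution

    if pi is None:
        if params.pi.ndim == 2 and params.pi.shape[0] == symbols.n_trials:
            pi = params.pi
        else:
            pi = stationary_distribution(params.Gamma)
    logB = mhmm_log_emission_matrix(symbols, params.E)
    return forward_backward(logB, params.Gamma, pi)
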