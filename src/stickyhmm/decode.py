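"""State decoding: per-bin posterior decoding and Viterbi paths.

Posterior decoding assigns each bin the state with the largest smoothed
posterior q_i(t); bins whose maximal posterior falls below a confidence
threshold (default 0.8) are left *undecided* and marked with -1.  Viterbi
decoding returns the jointly most probable path and never leaves undecided
bins.  Unless stated otherwise the initial distribution used for decoding
is the stationary distribution of the fitted transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinnedCounts
from .em import forward_backward, log_emission_matrix
from .params import HMMParams

__all__ = [
    "UNDECIDED",
    "DecodeResult",
    "posterior_decode",
    "viterbi_decode",
    "stationary_distribution",
]

#: marker for bins whose maximal posterior is below the decoding threshold
UNDECIDED = -1


@dataclass
class DecodeResult:
    """Decoded state sequences (trials x bins) plus the posteriors used.

    ``states`` uses 0-based state indices with ``UNDECIDED`` (-1) marking
    low-confidence bins; ``path_logprob`` is filled by Viterbi decoding
    only (log-probability of the returned path per trial).
    """

    states: np.ndarray
    posteriors: np.ndarray | None
    method: str
    threshold: float | None = None
    path_logprob: np.ndarray | None = None

    @property
    def n_undecided(self) -> int:
        return int(np.sum(self.states == UNDECIDED))

    def segments(self, trial: int):
        """(start_bin, end_bin, state) runs of constant state in one trial."""
        s = self.states[trial]
        out = []
        start = 0
        for t in range(1, len(s) + 1):
            if t == len(s) or s[t] != s[start]:
                out.append((start, t, int(s[start])))
                start = t
        return out


def stationary_distribution(Gamma: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Solves pi^T (I - Gamma + U) = 1^T where U is the all-ones matrix; for
    an ergodic chain this linear system has the unique stationary vector as
    its solution.
    """
    Gamma = np.asarray(Gamma, dtype=float)
    m = Gamma.shape[0]
    A = (np.eye(m) - Gamma + np.ones((m, m))).T
    try:
        pi = np.linalg.solve(A, np.ones(m))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "stationary distribution solve failed; the chain may be "
            "reducible or periodic"
        ) from exc
    if np.any(pi < -1e-9) or not np.isfinite(pi).all():
        raise np.linalg.LinAlgError(
            "stationary distribution is not a probability vector; the chain "
            "may be reducible"
        )
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _decode_pi(params: HMMParams, n_trials: int, start_state_one: bool):
    if start_state_one:
        pi = np.zeros(params.m)
        pi[0] = 1.0
        return pi
    return stationary_distribution(params.Gamma)


def posterior_decode(
    counts: BinnedCounts,
    params: HMMParams,
    threshold: float = 0.8,
    start_state_one: bool = False,
    preroll_bins: int = 0,
) -> DecodeResult:
    """Per-bin maximum-posterior decoding with an undecided marker.

    Ties in the argmax are broken towards the lowest state index.  With
    ``threshold=0`` every bin is decided (the convention used by the model
    comparison index).  When decoding with a fixed first state
    (``start_state_one``), the first ``preroll_bins`` bins serve as a
    burn-in for the arbitrary start and are marked undecided.
    """
    pi = _decode_pi(params, counts.n_trials, start_state_one)
    logB = log_emission_matrix(counts, params.Lambda, params.dt)
    fb = forward_backward(logB, params.Gamma, pi)
    states = np.argmax(fb.q, axis=2).astype(np.int64)
    if threshold > 0:
        states[fb.q.max(axis=2) < threshold] = UNDECIDED
    if start_state_one and preroll_bins > 0:
        states[:, :preroll_bins] = UNDECIDED
    return DecodeResult(
        states=states, posteriors=fb.q, method="posterior", threshold=threshold
    )


def viterbi_decode(
    counts: BinnedCounts, params: HMMParams, start_state_one: bool = False
) -> DecodeResult:
    """Most probable complete state path per trial (log-space Viterbi)."""
    pi = _decode_pi(params, counts.n_trials, start_state_one)
    logB = log_emission_matrix(counts, params.Lambda, params.dt)
    with np.errstate(divide="ignore"):
        logG = np.log(params.Gamma)
        logpi = np.log(pi)
    K, T, m = logB.shape
    states = np.empty((K, T), dtype=np.int64)
    path_lp = np.empty(K)
    for k in range(K):
        delta = logpi + logB[k, 0]
        back = np.empty((T, m), dtype=np.int64)
        for t in range(1, T):
            cand = delta[:, None] + logG  # (from, to)
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(m)] + logB[k, t]
        last = int(np.argmax(delta))
        path_lp[k] = delta[last]
        states[k, T - 1] = last
        for t in range(T - 2, -1, -1):
            states[k, t] = back[t + 1, states[k, t + 1]]
    return DecodeResult(
        states=states, posteriors=None, method="viterbi", path_logprob=path_lp
    )


def path_log_probability(
    counts: BinnedCounts, params: HMMParams, states: np.ndarray, start_state_one=False
) -> np.ndarray:
    """Joint log-probability of given state paths and the observations."""
    pi = _decode_pi(params, counts.n_trials, start_state_one)
    logB = log_emission_matrix(counts, params.Lambda, params.dt)
    with np.errstate(divide="ignore"):
        logG = np.log(params.Gamma)
        logpi = np.log(pi)
    K, T, _ = logB.shape
    out = np.empty(K)
    for k in range(K):
        s = states[k]
        lp = logpi[s[0]] + logB[k, 0, s[0]]
        lp += logG[s[:-1], s[1:]].sum() + logB[k, np.arange(1, T), s[1:]].sum()
        out[k] = lp
    return out
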