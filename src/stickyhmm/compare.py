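"""Model comparison: decoded squared-error distance, the rho index and
Hungarian state matching.

Two fitted HMMs can have near-identical likelihoods yet imply different
states or transition times.  The distance D(Theta) measures, on a held-out
set, the total squared difference between observed per-bin spike counts and
the counts implied by the decoded state's firing rates; the index
rho = D(Theta_1)/D(Theta_2) is ~1 when the two models imply the same
states, transitions and transition times on the same data.  When the
generating model is known it serves as Theta_2, and rho >= 1 quantifies the
excess unexplained variability of the fitted model.

States of two models are put in correspondence by minimum-cost assignment
(Hungarian algorithm) on the Euclidean distances between their firing-rate
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data import BinnedCounts
from .decode import posterior_decode
from .params import HMMParams

__all__ = [
    "ComparisonReport",
    "model_distance",
    "rho",
    "match_states",
    "shuffled_rho_null",
]


@dataclass
class ComparisonReport:
    """rho = D1/D2 plus the state matching between the two models."""

    D1: float
    D2: float
    rho: float
    matching: list  # (state in model 1, state in model 2, distance in spikes/s)
    shuffled_rho: np.ndarray | None = None
    exceedance_probability: float | None = None


def model_distance(counts: BinnedCounts, params: HMMParams) -> float:
    """Total decoded squared error D(Theta) in counts^2.

    Every bin is assigned its maximum-posterior state (no confidence
    threshold), and the model-implied count is that state's rate times dt.
    Should be computed on data not used to train ``params``.
    """
    dec = posterior_decode(counts, params, threshold=0.0)
    # expected counts of the decoded state: (K, T, N) -> align with counts
    lam_dt = (params.Lambda * params.dt).T  # (m, N)
    implied = lam_dt[dec.states]  # (K, T, N)
    resid = counts.counts.transpose(0, 2, 1) - implied
    return float(np.sum(resid**2))


def rho(
    counts: BinnedCounts, theta1: HMMParams, theta2: HMMParams
) -> ComparisonReport:
    """Comparison index rho(Theta1, Theta2) = D(Theta1)/D(Theta2).

    When ``theta2`` is the generating model, D(Theta2) reflects only the
    irreducible within-state Poisson variability (plus transitions falling
    inside bins), so rho >= 1 is expected for any fitted ``theta1``.
    """
    D1 = model_distance(counts, theta1)
    D2 = model_distance(counts, theta2)
    if D2 <= 0:
        raise ZeroDivisionError("D(Theta2) = 0: degenerate denominator")
    return ComparisonReport(
        D1=D1, D2=D2, rho=D1 / D2, matching=match_states(theta1.Lambda, theta2.Lambda)
    )


def match_states(lambda1: np.ndarray, lambda2: np.ndarray):
    """Hungarian matching of state firing-rate columns.

    Returns a list of ``(i, j, d)`` triples matching state i of the first
    model to state j of the second with Euclidean distance d (spikes/s);
    min(m1, m2) pairs are produced, surplus states stay unmatched.
    """
    lambda1 = np.asarray(lambda1)
    lambda2 = np.asarray(lambda2)
    if lambda1.shape[0] != lambda2.shape[0]:
        raise ValueError("both rate matrices must cover the same neurons")
    diff = lambda1[:, :, None] - lambda2[:, None, :]
    cost = np.sqrt((diff**2).sum(axis=0))  # (m1, m2)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j), float(cost[i, j])) for i, j in zip(rows, cols)]


def permutation_from_matching(matching, m: int) -> np.ndarray:
    """Permutation p with p[j] = state of model 1 matched to state j of model 2."""
    perm = np.arange(m)
    for i, j, _ in matching:
        perm[j] = i
    return perm


def shuffled_rho_null(
    counts: BinnedCounts,
    theta1: HMMParams,
    theta2: HMMParams,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> ComparisonReport:
    """Null distribution of rho under state-identity shuffles of theta1.

    Each shuffle permutes the state columns of Lambda_1 and independently
    permutes the off-diagonal entries within each row of Gamma_1 (diagonals
    and row sums preserved), then recomputes rho.  The exceedance
    probability is the fraction of shuffles with rho at or below the
    unshuffled value (a small value means the unshuffled model is genuinely
    closer to theta2 than chance state assignments).
    """
    rng = np.random.default_rng(seed)
    base = rho(counts, theta1, theta2)
    m = theta1.m
    vals = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(m)
        Lam = theta1.Lambda[:, perm]
        G = theta1.Gamma.copy()
        if m > 2:
            for i in range(m):
                off_idx = np.flatnonzero(np.arange(m) != i)
                G[i, off_idx] = G[i, off_idx[rng.permutation(m - 1)]]
        shuffled = HMMParams(
            pi=theta1.mean_pi(), Gamma=G, Lambda=Lam, dt=theta1.dt
        )
        vals[s] = rho(counts, shuffled, theta2).rho
    exceed = float(np.mean(vals <= base.rho))
    return ComparisonReport(
        D1=base.D1,
        D2=base.D2,
        rho=base.rho,
        matching=base.matching,
        shuffled_rho=vals,
        exceedance_probability=exceed,
    )
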