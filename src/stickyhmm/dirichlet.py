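"""MAP training of the Poisson HMM with a Dirichlet prior on transitions.

Each row Gamma_i of the transition matrix receives an independent Dirichlet
prior with concentration parameters a_i = {a_i1, ..., a_im}.  Large
diagonal concentrations nudge the self-transition probabilities towards
high values without the hard constraint of sticky training.  The
hyperparameters are chosen by fixing the prior *mode*: with all
off-diagonal a_ij equal to a_bar > 1 and a target diagonal mode gamma_bar,

    a_ii = 1 + gamma_bar (m - 1)(a_bar - 1) / (1 - gamma_bar),

so the modal transition row has mu_ii = gamma_bar.  With the defaults
gamma_bar = 0.9, a_bar = 1.1 this gives a_ii = 1 + 0.9 (m - 1); for m = 5,
a_ii = 4.6 with modes mu_ii = 0.9 and mu_ij = 0.025.

Training is EM for the posterior: the only change to Baum-Welch is the
transition update, which gains a_ij - 1 pseudo-counts, and the monitored
objective, which is the log-posterior LP = LL + sum_ij (a_ij - 1) log
gamma_ij (the Dirichlet normalising constants are dropped: they do not
depend on the parameters and cancel in every comparison at fixed prior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinnedCounts
from .em import FBResult, TrainResult, _run_em, m_step
from .params import HMMParams

__all__ = [
    "DirichletPrior",
    "build_prior",
    "prior_mode",
    "map_transition_update",
    "log_posterior",
    "train_dphmm",
]


@dataclass
class DirichletPrior:
    """Row-wise Dirichlet concentrations A = {a_ij} for the transition matrix."""

    A: np.ndarray
    gamma_bar: float | None = None
    a_bar: float | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        m = self.A.shape[0]
        if self.A.shape != (m, m):
            raise ValueError("A must be square")
        if np.any(self.A < 1.0 - 1e-12):
            raise ValueError("concentration parameters must be >= 1")

    @property
    def m(self) -> int:
        return self.A.shape[0]

    def log_prior(self, Gamma: np.ndarray) -> float:
        """Unnormalised log density sum_ij (a_ij - 1) log gamma_ij."""
        A1 = self.A - 1.0
        with np.errstate(divide="ignore"):
            lg = np.log(Gamma)
        terms = np.where(A1 > 0, A1 * lg, 0.0)
        return float(terms.sum())


def build_prior(m: int, gamma_bar: float = 0.9, a_bar: float = 1.1) -> DirichletPrior:
    """Construct the mode-targeting prior for ``m`` states."""
    if m < 2:
        raise ValueError("the prior needs at least 2 states")
    if not 0 < gamma_bar < 1:
        raise ValueError("gamma_bar must lie in (0, 1)")
    if a_bar <= 1:
        raise ValueError("a_bar must exceed 1")
    A = np.full((m, m), a_bar)
    a_ii = 1.0 + gamma_bar * (m - 1) * (a_bar - 1.0) / (1.0 - gamma_bar)
    np.fill_diagonal(A, a_ii)
    return DirichletPrior(A=A, gamma_bar=gamma_bar, a_bar=a_bar)


def prior_mode(prior: DirichletPrior) -> np.ndarray:
    """Row-wise mode mu_ij = (a_ij - 1) / (sum_k a_ik - m); needs a_ij > 1."""
    A = prior.A
    m = prior.m
    den = A.sum(axis=1) - m
    if np.any(den <= 0):
        raise ValueError("prior mode undefined: need sum_k a_ik > m in every row")
    return (A - 1.0) / den[:, None]


def map_transition_update(fb: FBResult, prior: DirichletPrior) -> np.ndarray:
    """MAP re-estimate of Gamma from E-step posteriors plus pseudo-counts."""
    A1 = prior.A - 1.0
    num = fb.xi.sum(axis=(0, 1)) + A1
    den = fb.q[:, :-1, :].sum(axis=(0, 1)) + A1.sum(axis=1)
    Gamma = num / den[:, None]
    return Gamma / Gamma.sum(axis=1, keepdims=True)


def log_posterior(loglik: float, Gamma: np.ndarray, prior: DirichletPrior) -> float:
    """LP = LL + sum_ij (a_ij - 1) log gamma_ij (normalising constant dropped).

    Returns -inf when some gamma_ij = 0 has a_ij > 1 (zero prior density).
    """
    return loglik + prior.log_prior(Gamma)


def train_dphmm(
    counts: BinnedCounts,
    init: HMMParams,
    prior: DirichletPrior | None = None,
    maxiter: int = 1000,
    tol: tuple = (1e-6, 1e-6),
    fixed_pi: bool = False,
) -> TrainResult:
    """MAP Baum-Welch with the Dirichlet transition prior.

    Identical to ML training except for the transition update and the
    monitored objective (the log-posterior), which is non-decreasing across
    iterations.  ``loglik_trajectory`` of the result stores LP; the final
    plain log-likelihood is kept in ``result.loglik``.
    """
    prior = prior or build_prior(init.m)
    if prior.m != init.m:
        raise ValueError("prior and initial guess disagree on the number of states")
    return _run_em(
        counts,
        init,
        maxiter=maxiter,
        tol=tol,
        prior_A=prior.A,
        log_prior_fn=prior.log_prior,
        fixed_pi=fixed_pi,
    )
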