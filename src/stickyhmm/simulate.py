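"""Ground-truth generators and controls.

The main surrogate is the multivariate Markov-modulated Poisson process
(MMPP): a continuous-time Markov chain whose states set per-neuron Poisson
firing rates.  The Poisson-HMM is the *true* model for this process, so
recovery of its parameters is a well-posed benchmark.  The chain is
simulated with the Gillespie algorithm: the per-bin transition matrix
``Gamma`` (referenced to a bin width ``dt_ref``) is read as a generator
with exit rate (1 - gamma_ii)/dt_ref from state i and jump law
gamma_ij / (1 - gamma_ii); within a dwell each neuron emits spikes with
exponential inter-spike intervals at its state rate.

The module also provides the standard random initial guesses for training
(a near-diagonal symmetric transition matrix plus rates drawn between the
empirical extremes), and the two surrogate controls: the circular shuffle
(which destroys spike-time coordination across neurons while preserving
each train's statistics) and the swap shuffle (which destroys temporal
order while preserving the multiset of population count vectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import BinnedCounts, SpikeDataset, Trial
from .decode import stationary_distribution
from .params import RATE_FLOOR, HMMParams, MHMMParams

__all__ = [
    "MMPPSpec",
    "random_mmpp_spec",
    "generate_mmpp",
    "random_init",
    "circular_shuffle",
    "swap_shuffle",
]


@dataclass
class MMPPSpec:
    """Specification of an MMPP surrogate session.

    ``Gamma`` is the per-bin transition matrix at reference bin width
    ``dt_ref`` (50 ms by default, matching the training bin width);
    ``Lambda`` holds state firing rates in spikes/s.
    """

    Gamma: np.ndarray
    Lambda: np.ndarray
    n_trials: int = 50
    trial_duration: float = 14.0
    dt_ref: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        if not np.allclose(self.Gamma.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("Gamma rows must sum to 1")
        if np.any(self.Lambda < 0):
            raise ValueError("rates must be non-negative")

    @property
    def m(self) -> int:
        return self.Gamma.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.Lambda.shape[0]

    def to_params(self) -> HMMParams:
        """The generating model as an HMM at the reference bin width."""
        return HMMParams(
            pi=stationary_distribution(self.Gamma),
            Gamma=self.Gamma,
            Lambda=np.clip(self.Lambda, RATE_FLOOR, None),
            dt=self.dt_ref,
        )


def random_mmpp_spec(
    m: int,
    n_neurons: int,
    n_trials: int = 50,
    trial_duration: float = 14.0,
    seed: int | None = None,
    diag_range: tuple = (0.8, 1.0),
    rate_range: tuple = (0.0, 30.0),
    dt_ref: float = 0.05,
) -> MMPPSpec:
    """Random session spec: diagonals ~ U(0.8, 1), rates ~ U(0, 30) spikes/s.

    Off-diagonal mass of each row is split among the other states by
    normalised uniform draws.
    """
    if m < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    diag = rng.uniform(*diag_range, size=m)
    Gamma = np.zeros((m, m))
    for i in range(m):
        w = rng.uniform(size=m - 1)
        off = (1.0 - diag[i]) * w / w.sum()
        Gamma[i, np.arange(m) != i] = off
        Gamma[i, i] = diag[i]
    Lambda = rng.uniform(*rate_range, size=(n_neurons, m))
    return MMPPSpec(
        Gamma=Gamma,
        Lambda=Lambda,
        n_trials=n_trials,
        trial_duration=trial_duration,
        dt_ref=dt_ref,
        seed=seed,
    )


def generate_mmpp(spec: MMPPSpec, seed: int | None = None):
    """Simulate the MMPP: returns (SpikeDataset, state paths).

    State paths are lists (one per trial) of ``(start_s, end_s, state)``
    tuples covering ``[0, trial_duration)``.  The initial state of each
    trial is drawn from the stationary distribution of Gamma.  A state with
    gamma_ii = 1 is absorbing: its dwell is capped at the trial end (with a
    warning).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    m, N = spec.m, spec.n_neurons
    diag = np.diag(spec.Gamma)
    exit_rate = (1.0 - diag) / spec.dt_ref
    if np.any(diag >= 1.0 - 1e-15):
        warnings.warn("absorbing state (gamma_ii = 1): dwell capped at trial end")
    try:
        pi0 = stationary_distribution(spec.Gamma)
    except np.linalg.LinAlgError:
        pi0 = np.full(m, 1.0 / m)

    trials = []
    paths = []
    for _ in range(spec.n_trials):
        t = 0.0
        state = int(rng.choice(m, p=pi0))
        path = []
        spikes = [[] for _ in range(N)]
        while t < spec.trial_duration:
            if exit_rate[state] > 0:
                dwell = rng.exponential(1.0 / exit_rate[state])
            else:
                dwell = np.inf
            end = min(t + dwell, spec.trial_duration)
            path.append((t, end, state))
            for n in range(N):
                lam = spec.Lambda[n, state]
                if lam <= 0:
                    continue
                # fresh exponential clock at the state switch (memoryless)
                s = t + rng.exponential(1.0 / lam)
                while s < end:
                    spikes[n].append(s)
                    s += rng.exponential(1.0 / lam)
            if end >= spec.trial_duration:
                break
            # jump law gamma_ij / (1 - gamma_ii)
            p = spec.Gamma[state].copy()
            p[state] = 0.0
            p /= p.sum()
            state = int(rng.choice(m, p=p))
            t = end
        trials.append(
            Trial(
                spikes=[np.sort(np.array(s)) for s in spikes],
                duration=spec.trial_duration,
            )
        )
        paths.append(path)
    return SpikeDataset(trials=trials, n_neurons=N), paths


def states_at_bins(paths, n_bins: int, dt: float) -> np.ndarray:
    """Ground-truth state of each bin (by the state occupying the bin centre)."""
    K = len(paths)
    out = np.zeros((K, n_bins), dtype=np.int64)
    for k, path in enumerate(paths):
        starts = np.array([p[0] for p in path])
        labels = np.array([p[2] for p in path])
        centres = (np.arange(n_bins) + 0.5) * dt
        idx = np.searchsorted(starts, centres, side="right") - 1
        out[k] = labels[np.clip(idx, 0, len(labels) - 1)]
    return out


def random_init(
    binned: BinnedCounts,
    m: int,
    model_kind: str = "poisson",
    seed: int | None = None,
    theta: float | None = None,
):
    """Standard random initial guess for training.

    The transition matrix is ``theta*I + (1-theta)*U`` where U is a
    row-normalised symmetric uniform matrix; theta defaults to 0.8 for the
    Poisson family and 0.9 for the categorical model.  Poisson rates are
    drawn uniformly between the lowest and highest per-neuron rates
    estimated from the data; the categorical emission rows put almost all
    mass on the silence symbol.  The initial state distribution is uniform
    (Poisson) or concentrated on state 1 (categorical).
    """
    rng = np.random.default_rng(seed)
    kind = model_kind.lower()
    if kind in ("poisson", "phmm", "sphmm", "dphmm"):
        theta = 0.8 if theta is None else theta
    elif kind in ("multinoulli", "mhmm", "categorical"):
        theta = 0.9 if theta is None else theta
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    if m == 1:
        Gamma = np.ones((1, 1))
    else:
        u = rng.uniform(size=(m, m))
        u = np.triu(u) + np.triu(u, 1).T  # symmetric draws u_ij = u_ji
        U = u / u.sum(axis=1, keepdims=True)
        Gamma = theta * np.eye(m) + (1.0 - theta) * U

    N = binned.n_neurons
    if kind in ("poisson", "phmm", "sphmm", "dphmm"):
        mean_rates = binned.counts.mean(axis=(0, 2)) / binned.dt  # per neuron
        lo, hi = float(mean_rates.min()), float(mean_rates.max())
        if hi <= lo:
            hi = lo + 1.0
        Lambda = np.clip(rng.uniform(lo, hi, size=(N, m)), RATE_FLOOR, None)
        pi = np.full(m, 1.0 / m)
        return HMMParams(pi=pi, Gamma=Gamma, Lambda=Lambda, dt=binned.dt)

    E = rng.uniform(0.0, 1.0, size=(m, N + 1)) * 1e-3
    E[:, N] = 1.0  # almost all mass on the silence symbol before normalising
    E /= E.sum(axis=1, keepdims=True)
    pi = np.zeros(m)
    pi[0] = 1.0
    return MHMMParams(pi=pi, Gamma=Gamma, E=E, dt=binned.dt)


def circular_shuffle(dataset: SpikeDataset, seed: int | None = None) -> SpikeDataset:
    """Independently rotate each spike train within its trial.

    Each (trial, neuron) spike train is shifted by an independent uniform
    offset modulo the trial duration, destroying coordination across
    neurons while preserving every train's spike count and inter-spike
    structure (up to the wrap point).
    """
    rng = np.random.default_rng(seed)
    trials = []
    for tr in dataset.trials:
        spikes = []
        for s in tr.spikes:
            off = rng.uniform(0.0, tr.duration)
            spikes.append(np.sort(np.mod(s + off, tr.duration)))
        trials.append(Trial(spikes=spikes, duration=tr.duration))
    return SpikeDataset(trials=trials, n_neurons=dataset.n_neurons)


def swap_shuffle(binned: BinnedCounts, seed: int | None = None) -> BinnedCounts:
    """Randomly permute the time bins of each trial (all neurons jointly).

    Preserves the multiset of population count vectors per trial exactly
    while destroying their temporal order, removing any slow state
    structure an HMM could latch onto.
    """
    rng = np.random.default_rng(seed)
    counts = binned.counts.copy()
    for k in range(binned.n_trials):
        perm = rng.permutation(binned.n_bins)
        counts[k] = counts[k][:, perm]
    return BinnedCounts(counts=counts, dt=binned.dt)
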