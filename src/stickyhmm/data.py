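"""Spike-train containers, binning and preprocessing.

The package works with three representations of an ensemble recording:

``SpikeDataset``
    Raw spike times, organised as trials x neurons.  This is what the
    simulators produce and what spike CSV files store.

``BinnedCounts``
    A dense ``(trials, neurons, bins)`` tensor of spike counts at a fixed
    bin width ``dt``.  All Poisson-family HMMs are trained on this.

``SymbolSequence``
    A per-bin categorical code in ``{1, ..., N+1}`` where symbol ``n <= N``
    means "neuron n fired (alone) in this bin" and ``N+1`` means silence.
    The Multinoulli HMM is trained on this; it requires very short bins.

All times are in seconds internally.  Neuron indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeDataset",
    "BinnedCounts",
    "SymbolSequence",
    "Trial",
    "bin_spikes",
    "filter_silent_neurons",
    "encode_symbols",
    "read_spikes_csv",
    "write_spikes_csv",
    "EmptyDatasetError",
]


class EmptyDatasetError(ValueError):
    """Raised when a preprocessing step removes every neuron (or trial)."""


@dataclass
class Trial:
    """Spike times of one trial: a list of per-neuron float arrays (seconds)."""

    spikes: list
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        for n, s in enumerate(self.spikes):
            if s.size and (s.min() < 0 or s.max() >= self.duration):
                raise ValueError(
                    f"spike times of neuron {n} outside [0, {self.duration})"
                )


@dataclass
class SpikeDataset:
    """An ensemble recording: a non-empty list of :class:`Trial` objects.

    Every trial must contain the same number of neurons ``n_neurons``;
    durations may vary across trials (simultaneously recorded sessions
    usually have equal-length trials).
    """

    trials: list
    n_neurons: int

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("dataset must contain at least one trial")
        for k, tr in enumerate(self.trials):
            if len(tr.spikes) != self.n_neurons:
                raise ValueError(
                    f"trial {k} has {len(tr.spikes)} neurons, expected {self.n_neurons}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def durations(self) -> np.ndarray:
        return np.array([tr.duration for tr in self.trials])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``trial, neuron, time_s``."""
        rows = []
        for k, tr in enumerate(self.trials):
            for n, s in enumerate(tr.spikes):
                for t in s:
                    rows.append((k, n, t))
        return pd.DataFrame(rows, columns=["trial", "neuron", "time_s"])

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        n_neurons: int | None = None,
        durations=None,
    ) -> "SpikeDataset":
        """Build a dataset from a ``trial, neuron, time_s`` table.

        ``durations`` may be a scalar (shared by all trials), a sequence per
        trial, or None (each trial's duration is the next bin-friendly value
        just above its last spike).
        """
        if n_neurons is None:
            n_neurons = int(df["neuron"].max()) + 1 if len(df) else 1
        trial_ids = sorted(df["trial"].unique()) if len(df) else [0]
        n_trials = int(max(trial_ids)) + 1 if trial_ids else 1
        if durations is None:
            durations = [
                float(df.loc[df["trial"] == k, "time_s"].max()) + 1e-9
                if (df["trial"] == k).any()
                else 1.0
                for k in range(n_trials)
            ]
        elif np.isscalar(durations):
            durations = [float(durations)] * n_trials
        trials = []
        for k in range(n_trials):
            sub = df[df["trial"] == k]
            spikes = [
                np.sort(sub.loc[sub["neuron"] == n, "time_s"].to_numpy(dtype=float))
                for n in range(n_neurons)
            ]
            trials.append(Trial(spikes=spikes, duration=float(durations[k])))
        return cls(trials=trials, n_neurons=n_neurons)

    def bin(self, dt: float) -> "BinnedCounts":
        return bin_spikes(self, dt)


@dataclass
class BinnedCounts:
    """Spike counts on a regular grid: ``counts[trial, neuron, bin]``."""

    counts: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (trials, neurons, bins) tensor")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def total_bins(self) -> int:
        """Total number of observations D across all trials."""
        return self.n_trials * self.n_bins

    def subset_trials(self, idx) -> "BinnedCounts":
        return BinnedCounts(counts=self.counts[np.asarray(idx)], dt=self.dt)

    def to_frame(self) -> pd.DataFrame:
        k, n, t = np.nonzero(self.counts)
        return pd.DataFrame(
            {"trial": k, "neuron": n, "bin": t, "count": self.counts[k, n, t]}
        )


@dataclass
class SymbolSequence:
    """Categorical per-bin observations, values in ``{1, ..., N+1}``."""

    symbols: np.ndarray
    dt: float
    n_neurons: int

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 2:
            raise ValueError("symbols must be a (trials, bins) array")
        if self.symbols.min(initial=1) < 1 or self.symbols.max(
            initial=1
        ) > self.n_neurons + 1:
            raise ValueError("symbols must lie in [1, N+1]")

    @property
    def n_trials(self) -> int:
        return self.symbols.shape[0]

    @property
    def n_bins(self) -> int:
        return self.symbols.shape[1]


def bin_spikes(dataset: SpikeDataset, dt: float) -> BinnedCounts:
    """Bin spike times into counts on half-open windows ``[t*dt, (t+1)*dt)``.

    A spike exactly at the trial end falls outside the last bin and is
    dropped.  When trial durations differ, all trials are truncated to the
    shortest trial's bin count so the result is rectangular (a warning is
    emitted).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_bins_per_trial = [int(np.floor(tr.duration / dt + 1e-12)) for tr in dataset.trials]
    n_bins = min(n_bins_per_trial)
    if n_bins < 1:
        raise ValueError("dt larger than the shortest trial")
    if len(set(n_bins_per_trial)) > 1:
        warnings.warn(
            "unequal trial durations: truncating all trials to "
            f"{n_bins} bins of {dt} s",
            stacklevel=2,
        )
    counts = np.zeros((dataset.n_trials, dataset.n_neurons, n_bins), dtype=np.int64)
    edges = np.arange(n_bins + 1) * dt
    for k, tr in enumerate(dataset.trials):
        for n, s in enumerate(tr.spikes):
            if s.size:
                counts[k, n], _ = np.histogram(s, bins=edges)
    return BinnedCounts(counts=counts, dt=dt)


def filter_silent_neurons(binned: BinnedCounts, min_rate: float = 1.0):
    """Drop neurons whose peak binned firing rate is below ``min_rate``.

    The peak rate of a neuron is ``max(count)/dt`` over all trials and bins.
    The comparison is strict ("lower than"), so a neuron peaking exactly at
    ``min_rate`` is retained.  Returns the filtered counts and the indices
    of the retained neurons in the original ordering.
    """
    peak_rate = binned.counts.max(axis=(0, 2)) / binned.dt
    kept = np.flatnonzero(peak_rate >= min_rate)
    if kept.size == 0:
        raise EmptyDatasetError(
            f"all {binned.n_neurons} neurons have peak rate < {min_rate} spikes/s"
        )
    return BinnedCounts(counts=binned.counts[:, kept, :], dt=binned.dt), kept.tolist()


def encode_symbols(binned: BinnedCounts, rng_seed=None) -> SymbolSequence:
    """Collapse binned counts into the one-spiking-neuron symbol code.

    Bins with no spikes map to the silence symbol ``N+1``; bins where exactly
    one neuron spikes map to that neuron's 1-based index (spike multiplicity
    is ignored); bins where several neurons spike map to one of the spiking
    neurons drawn uniformly at random (seeded).  Short bins (<= 10 ms) keep
    such collisions rare; a warning is emitted above that width.
    """
    if binned.dt > 0.01:
        warnings.warn(
            f"dt={binned.dt} s is long for a categorical spike code; "
            "multi-neuron bins will be common",
            stacklevel=2,
        )
    rng = np.random.default_rng(rng_seed)
    K, N, T = binned.counts.shape
    active = binned.counts > 0
    n_active = active.sum(axis=1)  # (K, T)
    symbols = np.full((K, T), N + 1, dtype=np.int64)
    one = n_active == 1
    symbols[one] = np.argmax(active, axis=1)[one] + 1
    multi_k, multi_t = np.nonzero(n_active > 1)
    for k, t in zip(multi_k, multi_t):
        choices = np.flatnonzero(active[k, :, t])
        symbols[k, t] = rng.choice(choices) + 1
    return SymbolSequence(symbols=symbols, dt=binned.dt, n_neurons=N)


def write_spikes_csv(dataset: SpikeDataset, path) -> None:
    """Write a dataset as a ``trial,neuron,time_s`` CSV with full precision."""
    df = dataset.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def read_spikes_csv(path, n_neurons=None, durations=None) -> SpikeDataset:
    # round_trip parsing: spike times written at full precision must come
    # back bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    return SpikeDataset.from_frame(df, n_neurons=n_neurons, durations=durations)
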