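"""Model classes with a statsmodels-flavoured fit/results interface.

Each model wraps binned spike counts (or a symbol sequence) and a choice of
number of hidden states; ``fit()`` runs EM from one or many seeded random
initial guesses and returns an :class:`HMMResults` carrying the winning
parameters, the training trajectory, convergence diagnostics and decoding
helpers.

    >>> counts = stickyhmm.bin_spikes(dataset, dt=0.05)
    >>> res = stickyhmm.StickyPoissonHMM(counts, n_states=3).fit(n_inits=10, seed=1)
    >>> print(res.summary())
    >>> decoded = res.decode()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import BinnedCounts, SpikeDataset, SymbolSequence, bin_spikes
from .dirichlet import DirichletPrior, build_prior, train_dphmm
from .em import TrainResult, score, train_phmm
from .multinoulli import rates_from_emissions, score_mhmm, train_mhmm
from .decode import posterior_decode, viterbi_decode
from .params import HMMParams, MHMMParams
from .simulate import random_init
from .sticky import StickyConfig, train_sphmm

__all__ = [
    "PoissonHMM",
    "StickyPoissonHMM",
    "DirichletPoissonHMM",
    "MultinoulliHMM",
    "HMMResults",
]


class HMMResults:
    """Fit results: parameters, diagnostics, decoding and scoring.

    Attributes
    ----------
    params : HMMParams or MHMMParams
        The winning fit (best objective across initial guesses).
    loglik : float
        Final log-likelihood (includes all constant terms).
    objective_trajectory : ndarray
        Monitored objective per EM iteration of the winning run (the
        log-posterior for the Dirichlet model, log-likelihood otherwise).
    converged : bool
    n_resets : int
        Sticky training only: number of snapshot resets of the winning run.
    all_results : list of TrainResult
        One entry per initial guess, in seed order.
    """

    def __init__(self, model, result: TrainResult, all_results):
        self.model = model
        self._result = result
        self.all_results = all_results

    @property
    def params(self):
        return self._result.params

    @property
    def loglik(self) -> float:
        return self._result.loglik

    @property
    def objective_trajectory(self) -> np.ndarray:
        return self._result.loglik_trajectory

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def n_iterations(self) -> int:
        return self._result.n_iterations

    @property
    def n_resets(self) -> int:
        return self._result.n_resets

    @property
    def min_self_transition(self) -> float:
        return self._result.min_self_transition

    @property
    def n_converged(self) -> int:
        return sum(r.converged for r in self.all_results)

    @property
    def firing_rates(self) -> np.ndarray:
        """(neurons, states) firing rates in spikes/s."""
        if isinstance(self.params, MHMMParams):
            return rates_from_emissions(self.params)
        return self.params.Lambda

    def score(self, data=None):
        """Log-likelihood of ``data`` (default: the training data)."""
        data = data if data is not None else self.model.data
        if isinstance(self.params, MHMMParams):
            return score_mhmm(data, self.params).loglik
        return score(data, self.params).loglik

    def decode(self, data=None, method: str = "posterior", threshold: float = 0.8):
        """Decode hidden states (Poisson-family models only)."""
        if isinstance(self.params, MHMMParams):
            raise NotImplementedError(
                "decode() on the categorical model: convert rates first"
            )
        data = data if data is not None else self.model.data
        if method == "posterior":
            return posterior_decode(data, self.params, threshold=threshold)
        if method == "viterbi":
            return viterbi_decode(data, self.params)
        raise ValueError(f"unknown decoding method {method!r}")

    def summary(self) -> str:
        p = self.params
        lines = [
            f"{type(self.model).__name__} fit: m={p.m} states, "
            f"N={p.n_neurons} neurons, dt={p.dt * 1000:.0f} ms",
            f"  log-likelihood      {self.loglik:.3f}",
            f"  converged           {self.converged} "
            f"({self.n_iterations} iterations"
            + (f", {self.n_resets} resets)" if self.n_resets else ")"),
            f"  min self-transition {self.min_self_transition:.4f}",
            f"  initial guesses     {len(self.all_results)} "
            f"({self.n_converged} converged)",
        ]
        diag = np.diag(p.Gamma)
        lines.append("  state self-transitions: "
                     + "  ".join(f"{d:.3f}" for d in diag))
        rates = self.firing_rates
        df = pd.DataFrame(
            rates,
            index=[f"neuron {n}" for n in range(rates.shape[0])],
            columns=[f"state {i}" for i in range(rates.shape[1])],
        )
        lines.append("  firing rates (spikes/s):")
        lines.append(df.round(2).to_string())
        return "\n".join(lines)

    def plot_decoding(self, trial: int = 0, ax=None):
        """Raster of one trial with decoded states shaded (needs matplotlib)."""
        import matplotlib.pyplot as plt

        dec = self.decode()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        dt = self.params.dt
        cmap = plt.get_cmap("tab10")
        for start, end, state in dec.segments(trial):
            if state >= 0:
                ax.axvspan(start * dt, end * dt, color=cmap(state % 10), alpha=0.3)
        counts = self.model.data.counts[trial]
        for n in range(counts.shape[0]):
            t = np.flatnonzero(counts[n]) * dt
            ax.plot(t, np.full_like(t, n, dtype=float), "|", color="k", ms=4)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("neuron")
        return ax


class _PoissonFamily:
    """Shared constructor/fit logic of the Poisson-family models."""

    _init_theta = 0.8

    def __init__(self, data, n_states: int, dt: float | None = None):
        if isinstance(data, SpikeDataset):
            if dt is None:
                dt = 0.05
            data = bin_spikes(data, dt)
        if not isinstance(data, BinnedCounts):
            raise TypeError("data must be a SpikeDataset or BinnedCounts")
        self.data = data
        self.n_states = int(n_states)
        if self.n_states < 1:
            raise ValueError("need at least one hidden state")

    @classmethod
    def from_dataframe(cls, df, n_states: int, dt: float = 0.05, durations=None, **kw):
        """Build from a long-format ``trial, neuron, time_s`` table."""
        ds = SpikeDataset.from_frame(df, durations=durations)
        return cls(bin_spikes(ds, dt), n_states, **kw)

    def _fit_single(self, init, maxiter, tol):  # overridden per model
        raise NotImplementedError

    def _make_init(self, seed):
        return random_init(
            self.data, self.n_states, model_kind="poisson", seed=seed,
            theta=self._init_theta,
        )

    def fit(
        self,
        n_inits: int = 1,
        seed: int | None = None,
        maxiter: int = 1000,
        tol: tuple = (1e-6, 1e-6),
    ) -> HMMResults:
        """Run EM from ``n_inits`` seeded random guesses; keep the best.

        The winning run is the converged fit with the highest final
        objective (falling back to the best non-converged fit if none
        converged, with ``converged=False``).
        """
        rng = np.random.default_rng(seed)
        results = []
        for _ in range(n_inits):
            s = int(rng.integers(2**31 - 1))
            init = self._make_init(s)
            results.append(self._fit_single(init, maxiter, tol, s))
        converged = [r for r in results if r.converged]
        pool = converged if converged else results
        best = max(pool, key=lambda r: r.loglik_trajectory[-1])
        return HMMResults(self, best, results)


class PoissonHMM(_PoissonFamily):
    """Poisson-emission HMM trained by maximum-likelihood Baum-Welch.

    Observations are per-bin spike-count vectors; in state i neuron n fires
    Poisson with mean ``lambda_ni * dt``, neurons conditionally independent
    given the state.
    """

    def _fit_single(self, init, maxiter, tol, seed):
        return train_phmm(self.data, init, maxiter=maxiter, tol=tol)


class StickyPoissonHMM(_PoissonFamily):
    """Poisson HMM whose training enforces self-transitions >= theta.

    See module ``sticky`` for the snapshot-reset-shuffle procedure; a
    converged fit is guaranteed to satisfy ``min_self_transition >= theta``.
    """

    def __init__(self, data, n_states, dt=None, theta: float = 0.8, epsilon: float = 5e-5):
        super().__init__(data, n_states, dt)
        self.theta = theta
        self.epsilon = epsilon
        self._init_theta = theta

    def _fit_single(self, init, maxiter, tol, seed):
        cfg = StickyConfig(
            theta=self.theta, epsilon=self.epsilon, maxiter=maxiter, tol=tol,
            rng_seed=seed,
        )
        return train_sphmm(self.data, init, cfg)


class DirichletPoissonHMM(_PoissonFamily):
    """Poisson HMM trained by MAP with a Dirichlet transition prior.

    The prior concentrates each transition row around a high self-transition
    mode ``gamma_bar`` (see module ``dirichlet``); ``fit`` monitors the
    log-posterior.
    """

    def __init__(self, data, n_states, dt=None, gamma_bar: float = 0.9, a_bar: float = 1.1):
        super().__init__(data, n_states, dt)
        self.prior = build_prior(max(self.n_states, 2), gamma_bar=gamma_bar, a_bar=a_bar)

    def _fit_single(self, init, maxiter, tol, seed):
        return train_dphmm(self.data, init, self.prior, maxiter=maxiter, tol=tol)


class MultinoulliHMM:
    """Categorical HMM on the one-spiking-neuron symbol code (short bins)."""

    def __init__(self, data: SymbolSequence, n_states: int):
        if not isinstance(data, SymbolSequence):
            raise TypeError("data must be a SymbolSequence (see encode_symbols)")
        self.data = data
        self.n_states = int(n_states)

    def fit(
        self,
        n_inits: int = 1,
        seed: int | None = None,
        maxiter: int = 1000,
        tol: tuple = (1e-6, 1e-6, 1e-6),
    ) -> HMMResults:
        rng = np.random.default_rng(seed)
        results = []
        # reuse the Poisson-count container only for shape information
        fake = BinnedCounts(
            counts=np.zeros(
                (self.data.n_trials, self.data.n_neurons, self.data.n_bins),
                dtype=np.int64,
            ),
            dt=self.data.dt,
        )
        for _ in range(n_inits):
            s = int(rng.integers(2**31 - 1))
            init = random_init(fake, self.n_states, model_kind="multinoulli", seed=s)
            results.append(train_mhmm(self.data, init, maxiter=maxiter, tol=tol))
        converged = [r for r in results if r.converged]
        pool = converged if converged else results
        best = max(pool, key=lambda r: r.loglik_trajectory[-1])
        return HMMResults(self, best, results)
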