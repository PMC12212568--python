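"""Parameter containers for the HMM family and their file round-trip.

A Poisson-family model is fully characterised by the transition matrix
``Gamma`` (m x m, row-stochastic) and the firing-rate matrix ``Lambda``
(N x m, spikes/s); the Multinoulli model replaces ``Lambda`` with a
row-stochastic emission matrix ``E`` of shape m x (N+1).  Initial state
probabilities ``pi`` are auxiliary: one vector per trial is carried during
training but the model is considered characterised by (Gamma, Lambda).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HMMParams", "MHMMParams", "save_params", "load_params", "RATE_FLOOR"]

#: smallest allowed firing rate (spikes/s); keeps Poisson emissions proper
RATE_FLOOR = 1e-3

_ATOL_ROW = 1e-10


def _check_stochastic(mat: np.ndarray, name: str) -> None:
    if np.any(mat < -1e-12) or np.any(mat > 1 + 1e-12):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(mat.sum(axis=-1), 1.0, atol=_ATOL_ROW):
        raise ValueError(f"{name} rows must sum to 1 within {_ATOL_ROW}")


@dataclass
class HMMParams:
    """Poisson-HMM parameters (pi, Gamma, Lambda) at bin width ``dt``.

    ``pi`` may be a single length-m vector or a (trials, m) array when a
    separate initial distribution is inferred per trial.
    """

    pi: np.ndarray
    Gamma: np.ndarray
    Lambda: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        m = self.Gamma.shape[0]
        if self.Gamma.shape != (m, m):
            raise ValueError("Gamma must be square")
        if self.Lambda.ndim != 2 or self.Lambda.shape[1] != m:
            raise ValueError("Lambda must be (n_neurons, m)")
        if self.pi.shape[-1] != m:
            raise ValueError("pi length must equal the number of states")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        _check_stochastic(self.Gamma, "Gamma")
        _check_stochastic(self.pi, "pi")
        if np.any(self.Lambda < RATE_FLOOR - 1e-12):
            raise ValueError(f"firing rates must be >= {RATE_FLOOR} spikes/s")

    @property
    def m(self) -> int:
        return self.Gamma.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.Lambda.shape[0]

    @property
    def min_self_transition(self) -> float:
        return float(np.min(np.diag(self.Gamma)))

    def pi_for_trial(self, k: int) -> np.ndarray:
        return self.pi if self.pi.ndim == 1 else self.pi[k]

    def mean_pi(self) -> np.ndarray:
        return self.pi if self.pi.ndim == 1 else self.pi.mean(axis=0)

    def permute_states(self, perm) -> "HMMParams":
        """Relabel states by ``perm`` (new index i holds old state perm[i])."""
        perm = np.asarray(perm)
        pi = self.pi[..., perm]
        return HMMParams(
            pi=pi,
            Gamma=self.Gamma[np.ix_(perm, perm)],
            Lambda=self.Lambda[:, perm],
            dt=self.dt,
        )


@dataclass
class MHMMParams:
    """Multinoulli-HMM parameters: emission rows over the N+1 symbols."""

    pi: np.ndarray
    Gamma: np.ndarray
    E: np.ndarray
    dt: float = 0.005

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        m = self.Gamma.shape[0]
        if self.Gamma.shape != (m, m):
            raise ValueError("Gamma must be square")
        if self.E.ndim != 2 or self.E.shape[0] != m:
            raise ValueError("E must be (m, n_symbols)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        _check_stochastic(self.Gamma, "Gamma")
        _check_stochastic(self.pi, "pi")
        _check_stochastic(self.E, "E")

    @property
    def m(self) -> int:
        return self.Gamma.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.E.shape[1] - 1

    @property
    def n_symbols(self) -> int:
        return self.E.shape[1]

    @property
    def min_self_transition(self) -> float:
        return float(np.min(np.diag(self.Gamma)))

    def pi_for_trial(self, k: int) -> np.ndarray:
        return self.pi if self.pi.ndim == 1 else self.pi[k]


def save_params(params, path) -> None:
    """Serialise parameters to JSON at full double precision."""
    if isinstance(params, HMMParams):
        obj = {
            "kind": "poisson",
            "m": params.m,
            "n_neurons": params.n_neurons,
            "dt": params.dt,
            "pi": params.pi.tolist(),
            "Gamma": params.Gamma.tolist(),
            "Lambda": params.Lambda.tolist(),
        }
    elif isinstance(params, MHMMParams):
        obj = {
            "kind": "multinoulli",
            "m": params.m,
            "n_neurons": params.n_neurons,
            "dt": params.dt,
            "pi": params.pi.tolist(),
            "Gamma": params.Gamma.tolist(),
            "E": params.E.tolist(),
        }
    else:
        raise TypeError(f"cannot serialise {type(params)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_params(path):
    with open(path) as fh:
        obj = json.load(fh)
    if obj["kind"] == "poisson":
        return HMMParams(
            pi=np.array(obj["pi"]),
            Gamma=np.array(obj["Gamma"]),
            Lambda=np.array(obj["Lambda"]),
            dt=obj["dt"],
        )
    if obj["kind"] == "multinoulli":
        return MHMMParams(
            pi=np.array(obj["pi"]),
            Gamma=np.array(obj["Gamma"]),
            E=np.array(obj["E"]),
            dt=obj["dt"],
        )
    raise ValueError(f"unknown parameter kind {obj['kind']!r}")
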