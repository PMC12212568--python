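"""Sticky Poisson-HMM training.

Plain Baum-Welch on spike counts often converges to solutions with
intermediate self-transition probabilities, which decode into rapid state
switching at time scales the data cannot support.  The sticky variant runs
ordinary EM while monitoring the diagonal of Gamma: whenever any
self-transition probability *converges* to a value below a threshold theta
(|gamma'_ii - gamma_ii| < epsilon AND gamma'_ii < theta), training restores
the most recent snapshot (Gamma*, Lambda*) taken at an iteration where all
gamma_ii >= theta, shuffles the firing-rate vectors of Lambda* across
states, and resumes.  A fit reported as converged therefore always has
min_i gamma_ii >= theta; if the shared iteration budget is exhausted first
the fit is reported as non-converged.

The threshold encodes a minimum expected state dwell time: a state with
self-transition gamma_ii has geometric dwell with mean dt/(1 - gamma_ii)
bins, so theta = 1 - dt/<T> enforces mean durations of at least <T>.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinnedCounts
from .em import TrainResult, _run_em
from .params import HMMParams

__all__ = ["StickyConfig", "train_sphmm", "theta_for_duration"]


@dataclass
class StickyConfig:
    """Knobs of the sticky training procedure.

    theta
        Self-transition threshold in (0, 1); 0.8 at 50 ms bins corresponds
        to state durations of at least 5 bins (250 ms).
    epsilon
        Tolerance deciding that an offending gamma_ii has *converged* below
        theta; transient dips below theta do not fire resets.
    """

    theta: float = 0.8
    epsilon: float = 5e-5
    maxiter: int = 1000
    tol: tuple = (1e-6, 1e-6)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def train_sphmm(
    counts: BinnedCounts, init: HMMParams, config: StickyConfig | None = None
) -> TrainResult:
    """Train a sticky Poisson HMM (snapshot-reset-shuffle procedure).

    The initial guess must satisfy min_i Gamma_ii >= theta (the standard
    random initialisation built with the same theta guarantees this), so a
    valid snapshot exists from iteration 0.  The returned result has
    ``converged=True`` only when EM converged at a point with all
    self-transitions at or above theta; the iteration budget is shared
    across resets.
    """
    config = config or StickyConfig()
    rng = np.random.default_rng(config.rng_seed)
    return _run_em(
        counts,
        init,
        maxiter=config.maxiter,
        tol=config.tol,
        sticky={"theta": config.theta, "epsilon": config.epsilon, "rng": rng},
    )


def theta_for_duration(dt: float, mean_duration: float) -> float:
    """Self-transition threshold enforcing a mean state duration.

    A state with self-transition probability gamma dwells for a geometric
    number of bins with mean dt/(1 - gamma); requiring mean durations of at
    least ``mean_duration`` gives theta = 1 - dt/mean_duration.  For
    example 50 ms bins and 250 ms durations give theta = 0.8 (5 bins).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= mean_duration:
        raise ValueError("dt must be smaller than the target mean duration")
    return 1.0 - dt / mean_duration
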