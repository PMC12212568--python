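"""Selecting the number of hidden states m.

Two families of criteria are provided:

* **Cross-validation** over trials: the dataset is split into folds, a
  model is trained on the complement of each fold from many random initial
  guesses, and the summed held-out log-likelihood LLv(m) is aggregated
  across folds and guesses.  Three rules then read off m*: the maximum of
  the mean curve (CV_max), the point of largest slope change (CV_slope),
  and the smallest m statistically indistinguishable from the best
  (CV_1SD).  For the Dirichlet model the held-out log-posterior LPv can be
  used in place of LLv.

* **Information criteria** on the full training set:
  BIC = -2 LL + K ln D and AIC = -2 LL + 2K with K = m(m-1) + mN free
  parameters (initial distributions excluded) and D the total number of
  bins over all trials.  "Modified" variants replace LL with the
  log-posterior LP.

Non-converged fits are excluded from all averages; their counts are
reported, since systematic non-convergence (e.g. on swap-shuffled data) is
itself diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BinnedCounts
from .dirichlet import build_prior, train_dphmm
from .em import score, train_phmm
from .params import HMMParams
from .simulate import random_init
from .sticky import StickyConfig, train_sphmm

__all__ = [
    "SelectionReport",
    "cross_validate",
    "pick_cv",
    "information_criteria",
    "select_best",
    "NoConvergedModelError",
]


class NoConvergedModelError(RuntimeError):
    """No initial guess converged at any candidate m."""


def _train_one(counts, m, model_kind, seed, maxiter, theta, prior_kwargs):
    init = random_init(counts, m, model_kind="poisson", seed=seed,
                       theta=theta if model_kind == "sphmm" else None)
    if model_kind == "phmm":
        return train_phmm(counts, init, maxiter=maxiter)
    if model_kind == "sphmm":
        cfg = StickyConfig(theta=theta, maxiter=maxiter, rng_seed=seed)
        return train_sphmm(counts, init, cfg)
    if model_kind == "dphmm":
        prior = build_prior(max(m, 2), **prior_kwargs)
        return train_dphmm(counts, init, prior, maxiter=maxiter)
    raise ValueError(f"unknown model kind {model_kind!r}")


@dataclass
class SelectionReport:
    """Score curves and the chosen m per criterion."""

    table: pd.DataFrame  # one row per m: mean/sd scores, convergence counts
    m_star: dict  # criterion -> m*
    best_model: dict  # criterion -> HMMParams (where applicable)
    model_kind: str = ""

    def __repr__(self) -> str:  # compact, table-first
        return f"SelectionReport(m_star={self.m_star})\n{self.table}"


def cross_validate(
    counts: BinnedCounts,
    model_kind: str = "sphmm",
    m_values=range(2, 9),
    n_folds: int = 5,
    n_inits: int = 100,
    seed: int | None = None,
    maxiter: int = 1000,
    theta: float = 0.8,
    use_log_posterior: bool = False,
    prior_kwargs: dict | None = None,
) -> SelectionReport:
    """Trial-level k-fold cross-validation of the held-out log-likelihood.

    Trials are shuffled once (seeded) and split into ``n_folds`` contiguous
    blocks.  For each fold and each candidate m, ``n_inits`` models are
    trained on the training trials; every converged fit contributes its
    summed validation log-likelihood LLv (initial distribution: stationary
    distribution of the fitted Gamma).  Mean and SD are pooled across folds
    and initial guesses.
    """
    m_values = list(m_values)
    K = counts.n_trials
    if K < n_folds:
        raise ValueError(f"need at least {n_folds} trials for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(K)
    folds = np.array_split(order, n_folds)
    prior_kwargs = prior_kwargs or {}

    rows = []
    best_by_m = {}
    for m in m_values:
        vals, lpvals = [], []
        n_conv = n_above = n_total = 0
        best_ll = -np.inf
        for fold in folds:
            train_idx = np.setdiff1d(order, fold)
            train = counts.subset_trials(train_idx)
            valid = counts.subset_trials(fold)
            for i in range(n_inits):
                n_total += 1
                s = int(rng.integers(2**31 - 1))
                res = _train_one(train, m, model_kind, s, maxiter, theta, prior_kwargs)
                if not res.converged:
                    continue
                n_conv += 1
                if res.min_self_transition >= theta:
                    n_above += 1
                llv = score(valid, res.params).loglik
                vals.append(llv)
                if use_log_posterior and model_kind == "dphmm":
                    prior = build_prior(max(m, 2), **prior_kwargs)
                    lpvals.append(llv + prior.log_prior(res.params.Gamma))
                if llv > best_ll:
                    best_ll = llv
                    best_by_m[m] = res.params
        vals = np.array(vals)
        row = {
            "m": m,
            "mean_LLv": vals.mean() if vals.size else np.nan,
            "sd_LLv": vals.std(ddof=1) if vals.size > 1 else 0.0,
            "n_converged": n_conv,
            "n_above_threshold": n_above,
            "n_total": n_total,
        }
        if use_log_posterior and lpvals:
            lp = np.array(lpvals)
            row["mean_LPv"] = lp.mean()
            row["sd_LPv"] = lp.std(ddof=1) if lp.size > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)

    m_star = {}
    best_model = {}
    for rule in ("max", "slope", "one_sd"):
        try:
            ms = pick_cv(table, rule)
        except ValueError:
            continue
        m_star[f"cv_{rule}"] = ms
        if ms in best_by_m:
            best_model[f"cv_{rule}"] = best_by_m[ms]
    return SelectionReport(
        table=table, m_star=m_star, best_model=best_model, model_kind=model_kind
    )


def pick_cv(report, rule: str = "max", column: str = "mean_LLv") -> int:
    """Read m* off a cross-validation curve.

    ``max``: argmax of the mean curve.  ``slope``: m with the largest
    decrease of the discrete slope, argmax_m [dLL(m) - dLL(m+1)] with
    dLL(m) = mean(m) - mean(m-1) (needs >= 3 candidate m).  ``one_sd``:
    smallest m whose mean + SD exceeds mean(m_best) - SD(m_best).
    """
    table = report.table if isinstance(report, SelectionReport) else report
    t = table.dropna(subset=[column]).reset_index(drop=True)
    if t.empty:
        raise ValueError("no m with a finite score")
    mvals = t["m"].to_numpy()
    mean = t[column].to_numpy()
    sd = t[column.replace("mean", "sd")].to_numpy()
    if rule == "max":
        return int(mvals[np.argmax(mean)])
    if rule == "slope":
        if len(mvals) < 3:
            raise ValueError("slope rule needs at least 3 candidate m values")
        d = np.diff(mean)  # d[i] = slope into m[i+1]
        drop = d[:-1] - d[1:]  # slope change at interior m[i+1]
        return int(mvals[1 + np.argmax(drop)])
    if rule == "one_sd":
        i_best = int(np.argmax(mean))
        floor = mean[i_best] - sd[i_best]
        ok = np.flatnonzero(mean + sd > floor)
        return int(mvals[ok[0]]) if ok.size else int(mvals[i_best])
    raise ValueError(f"unknown rule {rule!r}")


def n_parameters(m: int, n_neurons: int) -> int:
    """Free parameters K = m(m-1) + mN (initial distributions excluded)."""
    return m * (m - 1) + m * n_neurons


def information_criteria(
    loglik_train: float,
    m: int,
    n_neurons: int,
    n_bins_total: int,
    mode: str = "bic",
    log_prior: float = 0.0,
) -> float:
    """BIC/AIC score (lower is better); ``log_prior`` gives the modified form."""
    K = n_parameters(m, n_neurons)
    ll = loglik_train + log_prior
    if mode == "bic":
        return -2.0 * ll + K * np.log(n_bins_total)
    if mode == "aic":
        return -2.0 * ll + 2.0 * K
    raise ValueError(f"unknown mode {mode!r}")


def select_best(
    counts: BinnedCounts,
    model_kind: str = "sphmm",
    m_values=range(2, 9),
    criterion: str = "bic",
    n_inits: int = 25,
    seed: int | None = None,
    maxiter: int = 1000,
    theta: float = 0.8,
    modified: bool = False,
    prior_kwargs: dict | None = None,
):
    """Pick m by an information criterion on the full training set.

    For each m, ``n_inits`` models are trained on the whole dataset; scores
    of converged fits are averaged and m* minimises the mean score.  The
    returned model is the converged fit with the lowest score at m*.
    Returns ``(m_star, best_params, report)``.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic' here; use cross_validate for CV")
    rng = np.random.default_rng(seed)
    prior_kwargs = prior_kwargs or {}
    D = counts.total_bins
    rows = []
    best_at_m = {}
    for m in m_values:
        scores = []
        n_conv = n_above = 0
        best = (np.inf, None)
        for i in range(n_inits):
            s = int(rng.integers(2**31 - 1))
            res = _train_one(counts, m, model_kind, s, maxiter, theta, prior_kwargs)
            if not res.converged:
                continue
            n_conv += 1
            if res.min_self_transition >= theta:
                n_above += 1
            lp = 0.0
            if modified and model_kind == "dphmm":
                lp = build_prior(max(m, 2), **prior_kwargs).log_prior(res.params.Gamma)
            sc = information_criteria(
                res.loglik, m, counts.n_neurons, D, mode=criterion, log_prior=lp
            )
            scores.append(sc)
            if sc < best[0]:
                best = (sc, res.params)
        scores = np.array(scores)
        rows.append(
            {
                "m": m,
                f"mean_{criterion}": scores.mean() if scores.size else np.nan,
                f"sd_{criterion}": scores.std(ddof=1) if scores.size > 1 else 0.0,
                "n_converged": n_conv,
                "n_above_threshold": n_above,
                "n_total": n_inits,
            }
        )
        if best[1] is not None:
            best_at_m[m] = best
    table = pd.DataFrame(rows)
    finite = table.dropna(subset=[f"mean_{criterion}"])
    if finite.empty:
        raise NoConvergedModelError(
            f"no {model_kind} fit converged at any m in {list(m_values)}"
        )
    m_star = int(finite.loc[finite[f"mean_{criterion}"].idxmin(), "m"])
    best_params = best_at_m[m_star][1]
    report = SelectionReport(
        table=table,
        m_star={criterion: m_star},
        best_model={criterion: best_params},
        model_kind=model_kind,
    )
    return m_star, best_params, report
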