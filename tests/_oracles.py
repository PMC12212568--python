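"""Brute-force reference implementations used only to check the fast code.

Everything here enumerates explicitly (all state paths, all permutations)
or evaluates textbook formulas term by term, independent of the package's
scaled recursions.
"""

import itertools

import numpy as np
from scipy.stats import poisson


def poisson_log_emission_oracle(k, Lambda, dt):
    """Product of per-neuron Poisson pmfs, evaluated via scipy."""
    m = Lambda.shape[1]
    return np.array(
        [poisson.logpmf(k, Lambda[:, i] * dt).sum() for i in range(m)]
    )


def enumerate_paths(log_emissions, Gamma, pi):
    """Exact posteriors/loglik for ONE trial by summing over all m**T paths.

    ``log_emissions`` is (T, m).  Returns (q, xi, loglik) with q (T, m) and
    xi (T-1, m, m).
    """
    T, m = log_emissions.shape
    logG = np.log(Gamma)
    logpi = np.log(pi)
    joint = {}
    for path in itertools.product(range(m), repeat=T):
        lp = logpi[path[0]] + log_emissions[0, path[0]]
        for t in range(1, T):
            lp += logG[path[t - 1], path[t]] + log_emissions[t, path[t]]
        joint[path] = lp
    lps = np.array(list(joint.values()))
    c = lps.max()
    total = c + np.log(np.exp(lps - c).sum())
    q = np.zeros((T, m))
    xi = np.zeros((T - 1, m, m))
    for path, lp in joint.items():
        w = np.exp(lp - total)
        for t, s in enumerate(path):
            q[t, s] += w
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += w
    return q, xi, total


def viterbi_oracle(log_emissions, Gamma, pi):
    """argmax over all paths of the joint log-probability (one trial)."""
    T, m = log_emissions.shape
    logG = np.log(Gamma)
    logpi = np.log(pi)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(m), repeat=T):
        lp = logpi[path[0]] + log_emissions[0, path[0]]
        for t in range(1, T):
            lp += logG[path[t - 1], path[t]] + log_emissions[t, path[t]]
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


def hungarian_oracle(cost):
    """Minimum-cost square assignment by exhaustive permutation search."""
    m = cost.shape[0]
    best, best_c = None, np.inf
    for perm in itertools.permutations(range(m)):
        c = sum(cost[i, perm[i]] for i in range(m))
        if c < best_c:
            best, best_c = perm, c
    return np.array(best), best_c
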