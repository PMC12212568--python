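"""Clustered spiking network generating metastable ensemble activity.

A recurrent network of excitatory (E) and inhibitory (I) leaky
integrate-and-fire neurons in which a fraction ``f`` of the E population is
partitioned into ``Q`` clusters with potentiated within-cluster synapses
(factor ``J_plus``) and depressed between-cluster synapses (factor
``J_minus = max(1 - gamma (J_plus - 1) f / Q, 0)``).  With the default
parameters the clusters switch stochastically between high- and low-rate
epochs, producing the metastable state sequences that the HMMs in this
package are designed to segment.

Subthreshold dynamics (voltages in mV, times in ms, currents expressed as
voltage drive in mV/ms):

    dV/dt = -(V - V_L)/tau_a + I_rec/C + I_ext/C,

with exponential synaptic currents: each presynaptic spike from a type-b
neuron adds ``w_ij / tau_syn_b`` to the postsynaptic current, which decays
with time constant ``tau_syn_b``.  A spike fires when V crosses the
threshold; V is clamped at the reset for a 5 ms refractory period.
Integration is forward Euler (default step 0.005 ms).

The full-size network (4000 E / 1000 I) is expensive; ``SNNConfig.scale``
shrinks the population while scaling synaptic weights by 1/scale to
preserve the mean recurrent drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SpikeDataset, Trial

__all__ = ["SNNConfig", "simulate_snn", "lif_period"]


@dataclass
class SNNConfig:
    """Parameters of the clustered LIF network (defaults: full-size)."""

    n_exc: int = 4000
    n_inh: int = 1000
    p_ee: float = 0.2
    p_ei: float = 0.5  # I -> E connection probability
    p_ie: float = 0.5  # E -> I
    p_ii: float = 0.5
    w_ee: float = 0.0416
    w_ie: float = 0.0212
    w_ei: float = -0.0882
    w_ii: float = -0.0848
    sd_ee: float = 0.0028
    sd_ei: float = 0.0028
    sd_ie: float = 0.0020
    sd_ii: float = 0.0020
    n_clusters: int = 10
    j_plus: float = 2.2
    gamma: float = 0.5
    f_clustered: float = 0.9
    v_th_exc: float = -55.0
    v_th_inh: float = -58.0
    v_reset: float = -60.0
    v_leak: float = -60.0
    refractory_ms: float = 5.0
    tau_exc: float = 20.0
    tau_inh: float = 10.0
    tau_syn_exc: float = 8.0
    tau_syn_inh: float = 5.0
    capacitance: float = 1.0  # nF
    i_ext_exc: float = 0.3217  # nA
    i_ext_inh: float = 0.2080
    euler_dt_ms: float = 0.005
    duration: float = 10.0  # seconds
    scale: float = 1.0

    @property
    def j_minus(self) -> float:
        return max(1.0 - self.gamma * (self.j_plus - 1.0) * self.f_clustered / self.n_clusters, 0.0)

    def scaled(self):
        """(n_exc, n_inh, weight multiplier) after applying ``scale``."""
        ne = max(int(round(self.n_exc * self.scale)), self.n_clusters)
        ni = max(int(round(self.n_inh * self.scale)), 1)
        return ne, ni, 1.0 / self.scale


def _build_network(config: SNNConfig, rng: np.random.Generator):
    """Random connectivity in CSR-by-presynaptic-neuron layout."""
    ne, ni, wmul = config.scaled()
    n = ne + ni
    n_clustered = int(round(config.f_clustered * ne))
    per_cluster = n_clustered // config.n_clusters
    n_clustered = per_cluster * config.n_clusters
    cluster_of = np.full(n, -1, dtype=np.int64)
    cluster_of[:n_clustered] = np.repeat(np.arange(config.n_clusters), per_cluster)

    is_exc = np.zeros(n, dtype=np.bool_)
    is_exc[:ne] = True

    jm = config.j_minus
    indptr = np.zeros(n + 1, dtype=np.int64)
    idx_parts, w_parts = [], []
    for j in range(n):  # presynaptic
        pre_exc = j < ne
        if pre_exc:
            p_post_e, p_post_i = config.p_ee, config.p_ie
            mu_e, sd_e = config.w_ee, config.sd_ee
            mu_i, sd_i = config.w_ie, config.sd_ie
        else:
            p_post_e, p_post_i = config.p_ei, config.p_ii
            mu_e, sd_e = config.w_ei, config.sd_ei
            mu_i, sd_i = config.w_ii, config.sd_ii
        targets_e = np.flatnonzero(rng.random(ne) < p_post_e)
        targets_e = targets_e[targets_e != j]
        targets_i = ne + np.flatnonzero(rng.random(ni) < p_post_i)
        w_e = rng.normal(mu_e, sd_e, size=targets_e.size)
        w_i = rng.normal(mu_i, sd_i, size=targets_i.size)
        if pre_exc:
            cj = cluster_of[j]
            ct = cluster_of[targets_e]
            if cj >= 0:
                same = ct == cj
                w_e = np.where(same, w_e * config.j_plus, np.where(ct >= 0, w_e * jm, w_e))
            else:
                pass  # background E neuron: plain w_ee to everyone
        idx = np.concatenate([targets_e, targets_i])
        w = np.concatenate([w_e, w_i]) * wmul
        idx_parts.append(idx)
        w_parts.append(w)
        indptr[j + 1] = indptr[j] + idx.size
    indices = np.concatenate(idx_parts)
    weights = np.concatenate(w_parts)
    return ne, ni, cluster_of, is_exc, indptr, indices, weights


def _get_integrator():
    from numba import njit

    @njit(cache=True)
    def _integrate(
        v0,
        tau_m,
        v_th,
        v_leak,
        v_reset,
        i_ext,
        is_exc,
        indptr,
        indices,
        weights,
        tau_se,
        tau_si,
        dt,
        n_steps,
        refrac_steps,
        max_spikes,
    ):
        n = v0.size
        v = v0.copy()
        i_e = np.zeros(n)
        i_i = np.zeros(n)
        refrac = np.zeros(n, dtype=np.int64)
        dec_e = 1.0 - dt / tau_se
        dec_i = 1.0 - dt / tau_si
        spike_step = np.empty(max_spikes, dtype=np.int64)
        spike_neuron = np.empty(max_spikes, dtype=np.int64)
        n_spikes = 0
        for step in range(n_steps):
            for i in range(n):
                i_e[i] *= dec_e
                i_i[i] *= dec_i
                if refrac[i] > 0:
                    refrac[i] -= 1
                    v[i] = v_reset
                else:
                    v[i] += dt * (
                        -(v[i] - v_leak) / tau_m[i] + i_e[i] + i_i[i] + i_ext[i]
                    )
                    if not np.isfinite(v[i]):
                        raise FloatingPointError("membrane potential diverged")
            for i in range(n):
                if refrac[i] == 0 and v[i] >= v_th[i]:
                    if n_spikes >= max_spikes:
                        raise FloatingPointError("spike buffer overflow")
                    spike_step[n_spikes] = step
                    spike_neuron[n_spikes] = i
                    n_spikes += 1
                    v[i] = v_reset
                    refrac[i] = refrac_steps
                    amp = (1.0 / tau_se) if is_exc[i] else (1.0 / tau_si)
                    for kk in range(indptr[i], indptr[i + 1]):
                        tgt = indices[kk]
                        if is_exc[i]:
                            i_e[tgt] += weights[kk] * amp
                        else:
                            i_i[tgt] += weights[kk] * amp
        return spike_step[:n_spikes], spike_neuron[:n_spikes]

    return _integrate


def simulate_snn(
    config: SNNConfig | None = None,
    seed: int | None = None,
    record_neurons=None,
    trial_duration: float | None = None,
):
    """Simulate the network and return a SpikeDataset of recorded neurons.

    ``record_neurons`` selects which neurons enter the dataset; by default
    9 clustered E neurons spread over 5 clusters are recorded, emulating a
    small simultaneously recorded ensemble.  The continuous run is cut into
    consecutive trials of ``trial_duration`` seconds (default: 5 equal
    trials).  Also returns the cluster labels and the full spike arrays for
    diagnostics: ``(dataset, info)`` with ``info['cluster_of']``,
    ``info['spike_times_ms']``, ``info['spike_neurons']``.
    """
    config = config or SNNConfig()
    rng = np.random.default_rng(seed)
    ne, ni, cluster_of, is_exc, indptr, indices, weights = _build_network(config, rng)
    n = ne + ni

    tau_m = np.where(is_exc, config.tau_exc, config.tau_inh)
    v_th = np.where(is_exc, config.v_th_exc, config.v_th_inh)
    i_ext = np.where(
        is_exc,
        config.i_ext_exc / config.capacitance,
        config.i_ext_inh / config.capacitance,
    )
    dt = config.euler_dt_ms
    n_steps = int(round(config.duration * 1000.0 / dt))
    refrac_steps = int(round(config.refractory_ms / dt))
    v0 = rng.uniform(config.v_reset, v_th - 0.1)
    max_spikes = int(n * config.duration * 100) + 1000  # ~100 Hz headroom

    integrate = _get_integrator()
    spike_step, spike_neuron = integrate(
        v0,
        tau_m,
        v_th,
        config.v_leak,
        config.v_reset,
        i_ext,
        is_exc,
        indptr,
        indices,
        weights,
        config.tau_syn_exc,
        config.tau_syn_inh,
        dt,
        n_steps,
        refrac_steps,
        max_spikes,
    )
    spike_t_ms = spike_step * dt

    if record_neurons is None:
        # 9 neurons from 5 clusters (2,2,2,2,1), matching typical ensembles
        per_cluster = np.flatnonzero(cluster_of == 0).size
        picks = []
        for c in range(5):
            members = np.flatnonzero(cluster_of == c)
            take = 2 if c < 4 else 1
            picks.extend(rng.choice(members, size=take, replace=False))
        record_neurons = np.array(picks)
    record_neurons = np.asarray(record_neurons)

    if trial_duration is None:
        trial_duration = config.duration / 5.0
    n_trials = max(int(np.floor(config.duration / trial_duration + 1e-9)), 1)
    trials = []
    for k in range(n_trials):
        t0 = k * trial_duration * 1000.0
        t1 = t0 + trial_duration * 1000.0
        spikes = []
        for nn in record_neurons:
            mask = (spike_neuron == nn) & (spike_t_ms >= t0) & (spike_t_ms < t1)
            spikes.append(np.sort((spike_t_ms[mask] - t0) / 1000.0))
        trials.append(Trial(spikes=spikes, duration=trial_duration))
    dataset = SpikeDataset(trials=trials, n_neurons=len(record_neurons))
    info = {
        "cluster_of": cluster_of,
        "spike_times_ms": spike_t_ms,
        "spike_neurons": spike_neuron,
        "recorded": record_neurons,
        "n_exc": ne,
        "n_inh": ni,
    }
    return dataset, info


def lif_period(tau_m: float, v_leak: float, v_reset: float, v_th: float, drive: float, refractory_ms: float) -> float:
    """Closed-form inter-spike interval (ms) of an isolated LIF neuron.

    ``drive`` is I_ext/C in mV/ms.  The neuron must be suprathreshold
    (steady-state voltage above threshold).
    """
    v_inf = v_leak + tau_m * drive
    if v_inf <= v_th:
        raise ValueError("drive below rheobase: the neuron never fires")
    return tau_m * np.log((v_inf - v_reset) / (v_inf - v_th)) + refractory_ms
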