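"""Event-driven simulation of the LIF network with depressing/facilitating synapses.

The membrane potential of neuron i obeys

    tau_m dV_i/dt = -V_i + I_i^syn + I_i^b ,

spiking (reset to V_r) at V_th; the synaptic current is the in-degree
normalised sum of active transmitter fractions, I_i^syn =
(1/K_i^I) sum_j G_ij Y_ij.  Each synapse partitions its resources into
recovered (X), active (Y) and inactive (Z) fractions with X+Y+Z = 1;
a presynaptic spike releases u*X into Y, Y decays into Z with time
constant T^I and Z recovers with T^R.  Synapses onto inhibitory
neurons are facilitating: u relaxes to its baseline U with time
constant T^F and jumps by U(1-u) at each presynaptic spike
(update-then-use order); onto excitatory neurons u == U stays fixed.

The simulation is exact: between events every variable is advanced in
closed form and threshold crossings are located by guaranteed
bracketing with 1e-10 ms tolerance (see _kernels).  Channel noise, if
requested, draws each reset uniformly from [V_r - delta, V_r + delta].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import run_event_driven
from .constants import TAU_M, V_R, V_TH
from .netgen import NetworkRealization

__all__ = [
    "SpikeData",
    "StimulusProgram",
    "natural_period",
    "simulate",
    "synapse_free_evolution",
    "apply_spike_to_synapse",
]


def natural_period(i_b, tau_m: float = TAU_M, v_r: float = V_R, v_th: float = V_TH):
    """Inter-spike period of an isolated neuron with constant drive ``i_b`` (ms).

    Equals ``tau_m * ln((I - V_r) / (I - V_th))`` above threshold and
    infinity at or below it (the neuron never fires in isolation).
    """
    i_b = np.asarray(i_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        period = np.where(
            i_b > v_th,
            tau_m * np.log((i_b - v_r) / np.where(i_b > v_th, i_b - v_th, 1.0)),
            np.inf,
        )
    return float(period) if period.ndim == 0 else period


def synapse_free_evolution(y, z, dt, t_i, t_r, u=None, u_base=None, t_f=None):
    """Closed-form free evolution of one synapse over ``dt`` ms (no presynaptic spike).

    Returns ``(y', z', u')``; ``u'`` is ``u`` unchanged unless the
    facilitation parameters are given.
    """
    ey = math.exp(-dt / t_i)
    er = math.exp(-dt / t_r)
    if abs(t_i - t_r) > 1e-9:
        a = y * t_r / (t_i - t_r)
        z_new = (z - a) * er + a * ey
    else:
        z_new = (z + y * dt / t_i) * er
    u_new = u
    if u is not None and t_f is not None and u_base is not None:
        u_new = u_base + (u - u_base) * math.exp(-dt / t_f)
    return y * ey, z_new, u_new


def apply_spike_to_synapse(y, z, u, u_base, facilitating: bool):
    """Instantaneous synaptic update at a presynaptic spike.

    Facilitating synapses first update ``u <- u + U(1-u)`` and then use
    the updated value for the release ``Y <- Y + u X`` with
    ``X = 1 - Y - Z`` (update-then-use order).
    """
    if facilitating:
        u = u + u_base * (1.0 - u)
    release = u * (1.0 - y - z)
    return y + release, z, u


@dataclass
class StimulusProgram:
    """Perturbations applied after the burn-in: deletions, DC steps, reset noise."""

    deletions: tuple = ()
    #: list of (neuron_id, amplitude mV, t_on ms, t_off ms), times relative
    #: to the start of the recording window
    dc_steps: tuple = ()
    noise_delta: float = 0.0

    def validate(self, n: int) -> None:
        for nid in self.deletions:
            if not 0 <= nid < n:
                raise ValueError(f"invalid neuron id {nid} in deletions")
        for nid, _amp, t_on, t_off in self.dc_steps:
            if not 0 <= nid < n:
                raise ValueError(f"invalid neuron id {nid} in dc_steps")
            if not t_on < t_off:
                raise ValueError(f"dc step requires t_on < t_off, got ({t_on}, {t_off})")
        if self.noise_delta < 0:
            raise ValueError("noise_delta must be non-negative")
        if self.noise_delta > 0 and V_R + self.noise_delta >= V_TH:
            raise ValueError("noise_delta would allow resets at or above threshold")


@dataclass
class SpikeData:
    """Timestamped spikes plus optional sampled synaptic-resource traces."""

    times: np.ndarray                   # ms, nondecreasing
    ids: np.ndarray                     # int32 neuron ids
    duration: float                     # ms, length of the recording window
    n_neurons: int
    sample_times: np.ndarray | None = None
    #: mean recovered fraction over efferent synapses, (n_samples, n_monitored)
    xout: np.ndarray | None = None
    #: mean recovered fraction over afferent synapses
    xin: np.ndarray | None = None
    monitored: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be nondecreasing")
        if self.ids.size and (self.ids.min() < 0 or self.ids.max() >= self.n_neurons):
            raise ValueError("invalid neuron id in spikes")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def rate(self, neuron: int) -> float:
        """Mean firing rate of one neuron over the window, Hz."""
        return float((self.ids == neuron).sum()) / (self.duration / 1000.0)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time_ms\tneuron_id\n")
            for t, i in zip(self.times, self.ids):
                fh.write(f"{float(t)!r}\t{int(i)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, n_neurons: int | None = None,
                 duration: float | None = None) -> "SpikeData":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        times = df.iloc[:, 0].to_numpy(float)
        ids = df.iloc[:, 1].to_numpy(np.int32)
        if n_neurons is None:
            n_neurons = int(ids.max()) + 1 if ids.size else 0
        if duration is None:
            duration = float(times.max()) if times.size else 0.0
        return cls(times=times, ids=ids, duration=duration, n_neurons=n_neurons)


def _csr(n: int, key: np.ndarray, n_edges: int):
    order = np.argsort(key, kind="stable")
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(ptr, key + 1, 1)
    np.cumsum(ptr, out=ptr)
    return ptr, order.astype(np.int64)


def simulate(
    network: NetworkRealization,
    duration_ms: float,
    program: StimulusProgram | None = None,
    seed: int = 0,
    burn_in_ms: float = 10_000.0,
    monitor=None,
    sample_dt_ms: float = 1.0,
    v_init: np.ndarray | None = None,
) -> SpikeData:
    """Simulate the network for ``burn_in_ms + duration_ms`` and record the window.

    The burn-in runs under control conditions from random initial
    potentials (uniform in [V_r, V_th)) with X=1, Y=Z=0 and u=U; the
    perturbation program (deletions, DC steps) switches on at the start
    of the recording window, whose spike times are reported from 0.
    ``monitor`` is an optional sequence of neuron ids whose mean
    efferent/afferent recovered fractions X^OUT, X^IN are sampled every
    ``sample_dt_ms``.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    prog = program if program is not None else StimulusProgram()
    n = network.n
    prog.validate(n)

    E = network.n_edges
    epost = network.edge_post.astype(np.int64)
    epre = network.edge_pre.astype(np.int64)
    k_in = network.in_degree
    gnorm = network.coupling / np.maximum(k_in[epost], 1)
    ti = network.decay.copy()
    # guard the (measure-zero) resonance T^I == tau_m in the closed forms
    near = np.abs(ti - TAU_M) < 1e-6
    ti[near] = TAU_M + 1e-6
    tr = network.recovery
    tf = np.where(np.isnan(network.facilitation_tau), 1.0, network.facilitation_tau)
    hasf = (~np.isnan(network.facilitation_tau)).astype(np.uint8)
    uu0 = network.baseline_u

    in_ptr, in_idx = _csr(n, epost, E)
    out_ptr, out_idx = _csr(n, epre, E)

    # schedule: deletions at window start, DC steps at burn_in + t_on/off
    entries = []
    for nid in prog.deletions:
        entries.append((burn_in_ms, 2, nid, 0.0))
    for nid, amp, t_on, t_off in prog.dc_steps:
        entries.append((burn_in_ms + t_on, 0, nid, amp))
        entries.append((burn_in_ms + t_off, 1, nid, amp))
    entries.sort()
    sched_t = np.array([e[0] for e in entries], dtype=float)
    sched_kind = np.array([e[1] for e in entries], dtype=np.int64)
    sched_nrn = np.array([e[2] for e in entries], dtype=np.int64)
    sched_val = np.array([e[3] for e in entries], dtype=float)

    mon = np.asarray(sorted(monitor), dtype=np.int64) if monitor else np.empty(0, np.int64)
    mon_out_edges, mon_out_ptr = _edge_groups(mon, epre, out_ptr, out_idx)
    mon_in_edges, mon_in_ptr = _edge_groups(mon, epost, in_ptr, in_idx)
    eff_sample_dt = sample_dt_ms if mon.size else 0.0

    rng = np.random.default_rng(seed)
    if v_init is None:
        v_init = V_R + (V_TH - V_R) * rng.random(n)
    else:
        v_init = np.asarray(v_init, dtype=float).copy()
    kernel_seed = int(rng.integers(2**31))

    t_end = burn_in_ms + duration_ms
    max_spikes = max(200_000, int(n * t_end / 1000.0 * 60))
    while True:
        (spike_t, spike_id, n_spikes, xout, xin, samp_t, n_samp, status) = run_event_driven(
            network.excitability.astype(float),
            in_ptr, in_idx, out_ptr, out_idx,
            epost, gnorm, ti, tr, tf, uu0, hasf,
            v_init, uu0.copy(),
            t_end, burn_in_ms,
            sched_t, sched_kind, sched_nrn, sched_val,
            float(prog.noise_delta), kernel_seed % (2**31),
            mon_out_ptr, mon_out_edges, mon_in_ptr, mon_in_edges,
            eff_sample_dt,
            max_spikes,
            TAU_M, V_R, V_TH,
        )
        if status == 0:
            break
        max_spikes *= 2

    times = spike_t[:n_spikes]
    ids = spike_id[:n_spikes]
    keep = times >= burn_in_ms
    data = SpikeData(
        times=times[keep] - burn_in_ms,
        ids=ids[keep].astype(np.int32),
        duration=duration_ms,
        n_neurons=n,
        meta={"seed": seed, "burn_in_ms": burn_in_ms},
    )
    if mon.size:
        data.sample_times = samp_t[:n_samp]
        data.xout = xout[:n_samp]
        data.xin = xin[:n_samp]
        data.monitored = mon
    return data


def _edge_groups(neurons: np.ndarray, edge_key: np.ndarray, ptr: np.ndarray,
                 idx: np.ndarray):
    """Concatenated CSR edge groups (by the given incidence) for a neuron list."""
    groups = []
    gptr = [0]
    for nid in neurons:
        groups.append(idx[ptr[nid]:ptr[nid + 1]])
        gptr.append(gptr[-1] + (ptr[nid + 1] - ptr[nid]))
    edges = np.concatenate(groups) if groups else np.empty(0, np.int64)
    return edges.astype(np.int64), np.array(gptr, dtype=np.int64)
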