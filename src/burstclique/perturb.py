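"""Single-neuron perturbation protocols and driver-cell analysis.

Two protocols probe how much one neuron matters for the collective
dynamics, both over a fixed 84 s recording window compared against
control runs: single-neuron deletion (SND) removes the neuron —
it neither integrates nor transmits — and single-neuron stimulation
(SNS) injects a DC step onto its intrinsic excitability.  A neuron is
a *driver* when some perturbation changes the population-burst count
by at least 50% of the control mean and beyond three control standard
deviations (both gates applied conjunctively).  Drivers whose deletion
collapses the bursting are *hubs*; the remaining drivers are low
functionally connected (LC) cells, split into LC1 (can reduce the
activity, possibly also enhance) and LC2 (only enhances).

The module also extracts the functional clique: the ordered routes of
hub firings inside the 70 ms build-up window of each burst, with their
frequencies and inter-neuron delays, and monitors the synaptic
resources (mean recovered fraction X^OUT of the efferent synapses)
whose pre-burst maxima gate burst ignition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .burstdetect import BurstCatalog, detect_pbs, refine_buildup
from .dynamics import SpikeData, StimulusProgram, simulate
from .funconn import build_functional_graph
from .netgen import NetworkRealization

__all__ = [
    "BaselineStats",
    "PerturbationOutcome",
    "SweepResult",
    "DriverReport",
    "CliqueReport",
    "ResourceReport",
    "count_pbs",
    "baseline_variability",
    "snd_experiment",
    "sns_experiment",
    "sweep_sns",
    "classify_drivers",
    "extract_clique",
    "resource_monitor",
]

#: recording window used throughout the perturbation protocols, s
WINDOW_S = 84.0


@dataclass
class BaselineStats:
    mean: float
    sd: float
    counts: np.ndarray
    usable: bool   # False when the realization does not burst


@dataclass
class PerturbationOutcome:
    neuron: int
    protocol: str               # "SND" or "SNS"
    n_pb: int
    control_mean: float
    control_sd: float
    i_stim: float | None = None
    rate_hz: float | None = None  # stimulated neuron's firing rate (SNS)

    @property
    def relative_change(self) -> float:
        if self.control_mean == 0:
            return float("nan")
        return (self.n_pb - self.control_mean) / self.control_mean

    def significant(self, n_sd: float = 3.0) -> bool:
        return abs(self.n_pb - self.control_mean) > n_sd * self.control_sd


@dataclass
class SweepResult:
    neuron: int
    currents: np.ndarray
    n_pb: np.ndarray
    rates_hz: np.ndarray


@dataclass
class DriverReport:
    classes: dict                  # neuron id -> "hub" | "LC1" | "LC2" | "none"
    control_mean: float
    control_sd: float
    hub_set: tuple = ()
    lc1_set: tuple = ()
    lc2_set: tuple = ()

    def to_json_dict(self) -> dict:
        return {
            "control_mean": self.control_mean,
            "control_sd": self.control_sd,
            "classes": {str(k): v for k, v in self.classes.items()},
            "hubs": list(self.hub_set),
            "lc1": list(self.lc1_set),
            "lc2": list(self.lc2_set),
        }


@dataclass
class CliqueReport:
    hubs: tuple
    #: route -> occurrence count; a route is a tuple of (neuron, occurrence_idx)
    routes: dict
    #: route -> list of (pair, mean_delay_ms, sd_delay_ms) for successive firings
    delays: dict
    leader: int | None
    d_in_percent: dict
    n_pb: int

    def main_route(self):
        if not self.routes:
            return None
        return max(self.routes.items(), key=lambda kv: kv[1])[0]


@dataclass
class ResourceReport:
    neurons: tuple
    sample_times: np.ndarray
    xout: np.ndarray                  # (n_samples, n_neurons)
    xin: np.ndarray
    #: per neuron: array of pre-PB local maxima of X^OUT (one per usable PB)
    pre_pb_max: dict = field(default_factory=dict)
    #: per neuron: IGI (s) preceding each usable PB, aligned with pre_pb_max
    igi_s: dict = field(default_factory=dict)
    #: per neuron: minimal ignition value X^OUT* over observed PBs
    x_star: dict = field(default_factory=dict)


def count_pbs(network: NetworkRealization, program: StimulusProgram | None = None,
              window_s: float = WINDOW_S, seed: int = 0,
              burn_in_s: float = 10.0) -> tuple[int, SpikeData, BurstCatalog]:
    """Simulate one window and return (PB count, spikes, catalog)."""
    spikes = simulate(network, window_s * 1000.0, program=program, seed=seed,
                      burn_in_ms=burn_in_s * 1000.0)
    catalog = detect_pbs(spikes)
    return catalog.n_pb, spikes, catalog


def baseline_variability(network: NetworkRealization, n_runs: int = 100,
                         window_s: float = WINDOW_S, seed: int = 0,
                         burn_in_s: float = 10.0,
                         min_bursts: int = 5) -> BaselineStats:
    """PB-count statistics over independent initial conditions.

    Runs ``n_runs`` control simulations differing only in their random
    initial state and reports the mean and SD of the PB count; a
    realization whose mean count stays below ``min_bursts`` is flagged
    unusable (no bursting dynamics, or too few bursts to analyse).
    """
    rng = np.random.default_rng(seed)
    counts = np.empty(n_runs, dtype=int)
    for r in range(n_runs):
        run_seed = int(rng.integers(2**31))
        counts[r], _, _ = count_pbs(network, None, window_s, run_seed, burn_in_s)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_runs > 1 else 0.0
    return BaselineStats(mean=mean, sd=sd, counts=counts, usable=mean >= min_bursts)


def snd_experiment(network: NetworkRealization, neuron: int, baseline: BaselineStats,
                   window_s: float = WINDOW_S, seed: int = 0,
                   burn_in_s: float = 10.0) -> PerturbationOutcome:
    """Single-neuron deletion: count PBs with the neuron removed."""
    program = StimulusProgram(deletions=(neuron,))
    n_pb, _, _ = count_pbs(network, program, window_s, seed, burn_in_s)
    return PerturbationOutcome(neuron=neuron, protocol="SND", n_pb=n_pb,
                               control_mean=baseline.mean, control_sd=baseline.sd)


def sns_experiment(network: NetworkRealization, neuron: int, i_stim: float,
                   baseline: BaselineStats, window_s: float = WINDOW_S,
                   seed: int = 0, burn_in_s: float = 10.0) -> PerturbationOutcome:
    """Single-neuron stimulation: DC step ``i_stim`` for the whole window.

    The stimulation current replaces the neuron's intrinsic drive
    during the window (the step amplitude is ``i_stim - I_b``), so
    ``i_stim`` is the total drive the stimulated neuron experiences,
    matching the current sweep convention.
    """
    amp = i_stim - float(network.excitability[neuron])
    program = StimulusProgram(dc_steps=((neuron, amp, 0.0, window_s * 1000.0),))
    n_pb, spikes, _ = count_pbs(network, program, window_s, seed, burn_in_s)
    return PerturbationOutcome(neuron=neuron, protocol="SNS", n_pb=n_pb,
                               control_mean=baseline.mean, control_sd=baseline.sd,
                               i_stim=i_stim, rate_hz=spikes.rate(neuron))


def sweep_sns(network: NetworkRealization, neuron: int, baseline: BaselineStats,
              i_min: float = 14.5, i_max: float = 18.0, step: float = 0.015,
              window_s: float = WINDOW_S, seed: int = 0,
              burn_in_s: float = 10.0) -> SweepResult:
    """PB count and stimulated-neuron rate over a range of DC amplitudes."""
    currents = np.arange(i_min, i_max + step / 2, step)
    n_pb = np.empty(currents.size, dtype=int)
    rates = np.empty(currents.size)
    for k, cur in enumerate(currents):
        out = sns_experiment(network, neuron, float(cur), baseline, window_s,
                             seed, burn_in_s)
        n_pb[k] = out.n_pb
        rates[k] = out.rate_hz
    return SweepResult(neuron=neuron, currents=currents, n_pb=n_pb, rates_hz=rates)


def classify_drivers(snd_results: dict, sns_sweeps: dict, baseline: BaselineStats,
                     change_frac: float = 0.5, n_sd: float = 3.0) -> DriverReport:
    """Classify neurons as driver hubs, LC1/LC2 drivers, or non-drivers.

    A hub's deletion reduces the PB count by at least ``change_frac``
    of the control mean (and beyond the ``n_sd`` control band).  A
    non-hub is an LC driver when some stimulation current changes the
    count by at least ``change_frac`` (same significance gate); LC2
    drivers only ever increase the count, LC1 drivers can decrease it.
    """
    mean, sd = baseline.mean, baseline.sd
    if mean <= 0:
        raise ValueError("baseline has no bursting; classification undefined")
    classes: dict[int, str] = {}
    neurons = sorted(set(snd_results) | set(sns_sweeps))
    for nid in neurons:
        label = "none"
        snd = snd_results.get(nid)
        if snd is not None:
            decrease = (mean - snd.n_pb) / mean
            if decrease >= change_frac and (mean - snd.n_pb) > n_sd * sd:
                label = "hub"
        if label == "none" and nid in sns_sweeps:
            sw = sns_sweeps[nid]
            delta = sw.n_pb - mean
            sig = (np.abs(delta) >= change_frac * mean) & (np.abs(delta) > n_sd * sd)
            if np.any(sig):
                label = "LC2" if np.all(delta[sig] > 0) else "LC1"
        classes[nid] = label
    return DriverReport(
        classes=classes,
        control_mean=mean,
        control_sd=sd,
        hub_set=tuple(k for k, v in classes.items() if v == "hub"),
        lc1_set=tuple(k for k, v in classes.items() if v == "LC1"),
        lc2_set=tuple(k for k, v in classes.items() if v == "LC2"),
    )


def extract_clique(spikes: SpikeData, catalog: BurstCatalog, hub_set,
                   window_ms: float = 70.0, max_lag: int = 100,
                   align: str = "peak") -> CliqueReport:
    """Ordered hub-firing routes in the build-up windows, with delays.

    For each PB the hubs' spikes in the ``window_ms`` preceding the
    reference time form an ordered sequence; a hub firing several
    times contributes one element per occurrence.  Two PBs share a
    route iff these sequences are identical.  The leader is the hub
    with zero functional in-degree (within the hub set) in the
    first-spike build-up functional graph — the cell whose firing
    initialises every burst.

    ``align="peak"`` (default) references the 1 ms-refined PB peak, as
    appropriate for large networks where the burst culminates in a
    synchronous volley; ``align="offset"`` references the PB offset,
    suited to micro-fixtures whose whole burst is the causal chain.
    """
    hubs = tuple(sorted(hub_set))
    if align == "peak":
        refined, _windows = refine_buildup(spikes, catalog, window_ms=window_ms)
        refs = refined.pb_peak_refined
    elif align == "offset":
        # one closing bin past the offset keeps sub-threshold stragglers
        # of the same event inside its window
        refs = catalog.pb_offset + catalog.bin_ms
    else:
        raise ValueError("align must be 'peak' or 'offset'")
    route_counter: Counter = Counter()
    route_delays: dict = {}
    hub_surr = {nid: [] for nid in hubs}
    for ref in refs:
        seq = []
        for nid in hubs:
            t = spikes.spikes_of(nid)
            t = t[(t >= ref - window_ms) & (t < ref)]
            for occ, tk in enumerate(np.sort(t)):
                seq.append((float(tk), nid, occ))
                if occ == 0:
                    hub_surr[nid].append(float(tk))
        seq.sort()
        route = tuple((nid, occ) for _t, nid, occ in seq)
        if not route:
            continue
        route_counter[route] += 1
        deltas = np.diff([t for t, _n, _o in seq])
        route_delays.setdefault(route, []).append(deltas)

    delays = {}
    for route, dl in route_delays.items():
        arr = np.array(dl)   # (n_events, len(route)-1)
        entries = []
        for j in range(arr.shape[1]):
            pair = (route[j], route[j + 1])
            entries.append((pair, float(arr[:, j].mean()),
                            float(arr[:, j].std(ddof=1)) if arr.shape[0] > 1 else 0.0))
        delays[route] = entries

    # leader: zero functional in-degree among hubs in the first-spike graph
    hub_surr = {nid: np.array(v) for nid, v in hub_surr.items()}
    graph = build_functional_graph(hub_surr, spikes.duration, max_lag=max_lag)
    d_in = {nid: 0 for nid in hubs}
    for _src, dst, _tau, _c in graph.edges:
        d_in[dst] += 1
    denom = max(len(hubs) - 1, 1)
    d_in_pct = {nid: 100.0 * d / denom for nid, d in d_in.items()}
    active_hubs = [nid for nid in hubs if len(hub_surr[nid]) > 0]
    zero_in = [nid for nid in active_hubs if d_in[nid] == 0]
    leader = zero_in[0] if len(zero_in) >= 1 else None
    return CliqueReport(hubs=hubs, routes=dict(route_counter), delays=delays,
                        leader=leader, d_in_percent=d_in_pct, n_pb=len(refs))


def resource_monitor(network: NetworkRealization, neurons, window_s: float = WINDOW_S,
                     seed: int = 0, burn_in_s: float = 10.0,
                     sample_dt_ms: float = 1.0,
                     guard_ms: float = 50.0) -> ResourceReport:
    """Monitor X^OUT/X^IN for a neuron set and relate pre-burst maxima to IGIs.

    For every PB (after the first) the local maximum of X^OUT between
    ``guard_ms`` after the previous peak and the current peak is
    recorded together with the preceding IGI; the minimal ignition
    value X^OUT* is the smallest such maximum over observed PBs.
    Neurons without efferent (afferent) synapses get NaN traces.
    """
    neurons = tuple(sorted(neurons))
    spikes = simulate(network, window_s * 1000.0, seed=seed,
                      burn_in_ms=burn_in_s * 1000.0, monitor=neurons,
                      sample_dt_ms=sample_dt_ms)
    catalog = detect_pbs(spikes)
    report = ResourceReport(neurons=neurons, sample_times=spikes.sample_times,
                            xout=spikes.xout, xin=spikes.xin)
    peaks = catalog.pb_peak
    for col, nid in enumerate(neurons):
        maxima, igis = [], []
        trace = spikes.xout[:, col]
        if np.all(np.isnan(trace)):
            continue
        for k in range(1, peaks.size):
            lo, hi = peaks[k - 1] + guard_ms, peaks[k]
            sel = (spikes.sample_times > lo) & (spikes.sample_times <= hi)
            if not sel.any():
                continue
            maxima.append(float(np.nanmax(trace[sel])))
            igis.append((peaks[k] - peaks[k - 1]) / 1000.0)
        report.pre_pb_max[nid] = np.array(maxima)
        report.igi_s[nid] = np.array(igis)
        report.x_star[nid] = float(np.min(maxima)) if maxima else float("nan")
    return report
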