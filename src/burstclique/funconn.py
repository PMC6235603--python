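"""Directed functional connectivity from spike timestamps.

Spike trains are binarised at 1 ms and, for every neuron pair, the
normalised cross-correlogram

    C_ab(tau) = sum_t a_{t+tau} b_t / min(sum a, sum b)

is evaluated on lags |tau| <= max_lag.  A directed functional edge is
assigned only when the correlogram is compatible neither with
uncorrelated firing (a flat correlogram) nor with synchronous firing
(a zero-centred symmetric correlogram): the lag-coincidence sample is
tested against a uniform lag law (Kolmogorov-Smirnov) and against a
zero mean (Student's t), both at the 5% level, and the edge direction
follows the sign of the correlogram peak (tau_max > 0: from b to a).

Surrogate timestamp constructions restrict the analysis to the
dynamics of interest: ``degree`` keeps one spike per burst (35 ms
minimum interval), ``buildup`` keeps each neuron's first spike in the
70 ms window preceding a burst peak, ``interburst`` keeps the activity
outside the bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .burstdetect import BurstCatalog
from .dynamics import SpikeData

__all__ = [
    "FunctionalGraph",
    "make_surrogate",
    "binarize",
    "cross_correlation",
    "lag_coincidences",
    "assign_edge",
    "build_functional_graph",
    "functional_degrees",
]


@dataclass
class FunctionalGraph:
    """Directed functional edges with lags, and per-neuron functional degrees."""

    n: int
    #: list of (src, dst, tau_ms, c_peak)
    edges: list = field(default_factory=list)
    #: neurons with no retained events (no edge evaluated)
    silent: list = field(default_factory=list)

    def out_degree_percent(self) -> np.ndarray:
        d = np.zeros(self.n)
        for src, _dst, _tau, _c in self.edges:
            d[src] += 1
        return 100.0 * d / (self.n - 1)

    def in_degree_percent(self) -> np.ndarray:
        d = np.zeros(self.n)
        for _src, dst, _tau, _c in self.edges:
            d[dst] += 1
        return 100.0 * d / (self.n - 1)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("src\tdst\ttau_ms\tc_peak\n")
            for src, dst, tau, c in self.edges:
                fh.write(f"{src}\t{dst}\t{tau}\t{c}\n")


def make_surrogate(spikes: SpikeData, mode: str, catalog: BurstCatalog | None = None,
                   min_isi_ms: float = 35.0, window_ms: float = 70.0) -> dict:
    """Mode-specific filtered timestamps, as a dict ``{neuron_id: times}``.

    ``degree``: sequentially keep a spike only if it falls at least
    ``min_isi_ms`` after the previously kept one (so only the first
    spike of each burst survives).  ``buildup``: each neuron's first
    spike within the ``window_ms`` preceding each PB peak (refined
    peaks when available).  ``interburst``: all spikes outside the PB
    onset-offset spans.
    """
    if mode not in ("degree", "buildup", "interburst"):
        raise ValueError(f"unknown surrogate mode {mode!r}")
    if mode in ("buildup", "interburst") and catalog is None:
        raise ValueError(f"mode {mode!r} requires a BurstCatalog")
    out: dict[int, np.ndarray] = {}
    if mode == "degree":
        for nid in range(spikes.n_neurons):
            t = spikes.spikes_of(nid)
            kept = []
            last = -np.inf
            for tk in t:
                if tk - last >= min_isi_ms:
                    kept.append(tk)
                    last = tk
            out[nid] = np.array(kept)
    elif mode == "buildup":
        peaks = (catalog.pb_peak_refined
                 if catalog.pb_peak_refined is not None else catalog.pb_peak)
        firsts: dict[int, list] = {nid: [] for nid in range(spikes.n_neurons)}
        for peak in peaks:
            mask = (spikes.times >= peak - window_ms) & (spikes.times < peak)
            seen: set[int] = set()
            for t, nid in zip(spikes.times[mask], spikes.ids[mask]):
                if int(nid) not in seen:
                    seen.add(int(nid))
                    firsts[int(nid)].append(float(t))
        out = {nid: np.array(v) for nid, v in firsts.items()}
    else:  # interburst
        outside = np.ones(spikes.n_spikes, dtype=bool)
        for s, e in zip(catalog.pb_onset, catalog.pb_offset):
            outside &= ~((spikes.times >= s) & (spikes.times < e))
        for nid in range(spikes.n_neurons):
            out[nid] = spikes.times[outside & (spikes.ids == nid)]
    return out


def binarize(times: np.ndarray, duration_ms: float, bin_ms: float = 1.0) -> np.ndarray:
    """0/1 series at ``bin_ms`` resolution (multiple events in a bin collapse)."""
    n_bins = int(np.ceil(duration_ms / bin_ms))
    series = np.zeros(n_bins, dtype=np.int8)
    if len(times):
        idx = np.minimum((np.asarray(times) / bin_ms).astype(np.int64), n_bins - 1)
        series[idx] = 1
    return series


def cross_correlation(a: np.ndarray, b: np.ndarray, max_lag: int = 500):
    """Normalised cross-correlogram of two binary series.

    Returns ``(lags, C)`` with ``C[tau] = sum_t a[t+tau] b[t] /
    min(sum a, sum b)`` for integer lags in [-max_lag, max_lag].
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError("series must have equal duration")
    n_min = min(int(a.sum()), int(b.sum()))
    if n_min == 0:
        raise ValueError("cross-correlation undefined for a series with no events")
    full = np.correlate(a.astype(float), b.astype(float), mode="full")
    center = b.size - 1
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.zeros(lags.size)
    valid = (lags >= -center) & (lags <= center)
    c[valid] = full[center + lags[valid]]
    return lags, c / n_min


def lag_coincidences(times_a: np.ndarray, times_b: np.ndarray, max_lag: int = 500,
                     bin_ms: float = 1.0) -> np.ndarray:
    """Integer lag (a minus b, in bins) of every coincidence within ±max_lag.

    Sparse equivalent of the correlogram: the multiset of lags whose
    histogram, divided by min(n_a, n_b), is C_ab(tau).
    """
    ia = np.unique((np.asarray(times_a) / bin_ms).astype(np.int64))
    ib = np.unique((np.asarray(times_b) / bin_ms).astype(np.int64))
    if ia.size == 0 or ib.size == 0:
        return np.empty(0, dtype=np.int64)
    lo = np.searchsorted(ib, ia - max_lag, side="left")
    hi = np.searchsorted(ib, ia + max_lag, side="right")
    out = []
    for k in range(ia.size):
        if hi[k] > lo[k]:
            out.append(ia[k] - ib[lo[k]:hi[k]])
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def assign_edge(lag_sample: np.ndarray, max_lag: int = 500, alpha: float = 0.05):
    """Decide whether a lag-coincidence sample supports a directed edge.

    Rejects (jointly, both at ``alpha``) the uncorrelated null (lags
    uniform on [-max_lag, max_lag], Kolmogorov-Smirnov) and the
    synchronous null (zero-centred lag distribution, Student's t on the
    mean).  Returns ``(direction, tau_max, c_peak_count)`` where
    direction is +1 for "b before a" (tau_max > 0), -1 for the reverse,
    or ``None`` when no edge is assigned.  Ties for the peak go to the
    smaller |tau|; an unresolved +/- tie or a zero-lag peak assigns no
    edge.
    """
    lag_sample = np.asarray(lag_sample)
    if lag_sample.size < 2:
        return None
    lags, counts = np.unique(lag_sample, return_counts=True)
    # peak with smallest |tau| tie-break
    cmax = counts.max()
    best = lags[counts == cmax]
    amin = np.abs(best).min()
    cands = best[np.abs(best) == amin]
    if cands.size > 1:
        return None   # unresolved +/- tie for the peak
    tau_max = int(cands[0])
    if tau_max == 0:
        return None
    # uniform-lag null (uncorrelated firing)
    span = max_lag + 0.5
    ks = stats.kstest(lag_sample, stats.uniform(loc=-span, scale=2 * span).cdf)
    if ks.pvalue >= alpha:
        return None
    # zero-centred null (synchronous firing)
    if np.all(lag_sample == lag_sample[0]):
        t_reject = lag_sample[0] != 0
    else:
        tt = stats.ttest_1samp(lag_sample, 0.0)
        t_reject = tt.pvalue < alpha
    if not t_reject:
        return None
    direction = 1 if tau_max > 0 else -1
    return direction, int(tau_max), int(cmax)


def build_functional_graph(timestamps: dict, duration_ms: float, max_lag: int = 500,
                           alpha: float = 0.05, bin_ms: float = 1.0) -> FunctionalGraph:
    """Directed functional graph over all neuron pairs.

    ``timestamps`` maps neuron id to (surrogate) spike times; neurons
    without events are flagged silent and take part in no edge.  Each
    unordered pair contributes at most one directed edge.
    """
    ids = sorted(timestamps)
    n = max(ids) + 1 if ids else 0
    graph = FunctionalGraph(n=n)
    active = [i for i in ids if len(timestamps[i]) > 0]
    graph.silent = [i for i in ids if len(timestamps[i]) == 0]
    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            a, b = active[ai], active[bi]
            sample = lag_coincidences(timestamps[a], timestamps[b], max_lag, bin_ms)
            if sample.size == 0:
                continue
            res = assign_edge(sample, max_lag=max_lag, alpha=alpha)
            if res is None:
                continue
            direction, tau_max, cpeak = res
            n_min = min(len(np.unique((np.asarray(timestamps[a]) / bin_ms).astype(int))),
                        len(np.unique((np.asarray(timestamps[b]) / bin_ms).astype(int))))
            c_val = cpeak / n_min
            if direction > 0:   # tau_max > 0: b fires first, edge b -> a
                graph.edges.append((b, a, tau_max, c_val))
            else:
                graph.edges.append((a, b, -tau_max, c_val))
    return graph


def functional_degrees(graph: FunctionalGraph, n: int | None = None,
                       hub_percentile: float = 90.0):
    """Per-neuron functional degrees in percent, plus hub labels.

    Degrees are percentages of the ``n - 1`` potential partners; hubs
    are neurons at or above the ``hub_percentile`` of the out-degree
    distribution (and with at least one functional target).
    """
    if n is None:
        n = graph.n
    d_out = graph.out_degree_percent()
    d_in = graph.in_degree_percent()
    thresh = np.percentile(d_out, hub_percentile)
    hubs = np.nonzero((d_out >= thresh) & (d_out > 0))[0]
    return d_out, d_in, hubs
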