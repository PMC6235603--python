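"""Population-burst and aborted-burst detection and burst statistics.

A population burst (PB) is detected on a 10 ms binning of the spike
raster whenever the number of *distinct* neurons firing in a bin
strictly exceeds 25% of the population; consecutive suprathreshold
bins merge into one event whose width is the onset-to-offset span of
the merged run.  Aborted bursts (ABs) are sub-threshold collective
enhancements: local maxima of the binned participation that stand out
of the inter-burst baseline but never reach the PB criterion.  The
module also provides the 1 ms build-up refinement around each PB peak,
the phase indicator that tracks event-rate changes against a control
inter-burst interval, the Kolmogorov-Smirnov comparison of IGI
distributions across stimulation epochs, and the PB-participation
similarity clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dynamics import SpikeData

logger = logging.getLogger(__name__)

__all__ = [
    "BurstCatalog",
    "PhaseTrace",
    "detect_pbs",
    "refine_buildup",
    "detect_abs",
    "event_participation",
    "phase_indicator",
    "compare_igi_epochs",
    "rolling_mean_igi",
    "participation_similarity",
]


@dataclass
class BurstCatalog:
    """Detected population bursts and aborted bursts for one recording."""

    pb_peak: np.ndarray          # ms, peak-bin centres, strictly increasing
    pb_onset: np.ndarray         # ms
    pb_offset: np.ndarray        # ms
    pb_participants: list        # list of int arrays (distinct neuron ids)
    ab_peak: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_total: int = 0
    bin_ms: float = 10.0
    #: 1 ms-refined peak times (filled by refine_buildup), ms
    pb_peak_refined: np.ndarray | None = None

    @property
    def n_pb(self) -> int:
        return self.pb_peak.size

    @property
    def n_ab(self) -> int:
        return self.ab_peak.size

    @property
    def pb_width(self) -> np.ndarray:
        return self.pb_offset - self.pb_onset

    @property
    def igi_s(self) -> np.ndarray:
        """Inter-burst intervals between consecutive PB peaks, seconds."""
        return np.diff(self.pb_peak) / 1000.0

    @property
    def t_g(self) -> np.ndarray:
        """PB peak times (the model analogue of GDP time stamps), ms."""
        return self.pb_peak

    def participation_fraction(self) -> np.ndarray:
        """Per-PB fraction of the population taking part in the burst."""
        return np.array([p.size / self.n_total for p in self.pb_participants])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("type\tpeak_ms\tonset_ms\toffset_ms\twidth_ms\tn_participants\n")
            for k in range(self.n_pb):
                fh.write(
                    f"PB\t{self.pb_peak[k]}\t{self.pb_onset[k]}\t{self.pb_offset[k]}"
                    f"\t{self.pb_offset[k] - self.pb_onset[k]}"
                    f"\t{self.pb_participants[k].size}\n"
                )
            for t in self.ab_peak:
                fh.write(f"AB\t{t}\t\t\t\t\n")

    def summary(self) -> dict:
        igi = self.igi_s
        width = self.pb_width
        return {
            "n_pb": int(self.n_pb),
            "n_ab": int(self.n_ab),
            "ab_pb_percent": 100.0 * self.n_ab / self.n_pb if self.n_pb else float("nan"),
            "igi_mean_s": float(igi.mean()) if igi.size else float("nan"),
            "igi_sd_s": float(igi.std(ddof=1)) if igi.size > 1 else float("nan"),
            "width_mean_ms": float(width.mean()) if width.size else float("nan"),
            "width_sd_ms": float(width.std(ddof=1)) if width.size > 1 else float("nan"),
            "participation_mean_percent": (
                100.0 * float(self.participation_fraction().mean()) if self.n_pb else float("nan")
            ),
        }


@dataclass
class PhaseTrace:
    """Phase indicator per event index and the control-mean IGI it refers to."""

    phi: np.ndarray
    delta_t: float


def _binned_participation(spikes: SpikeData, bin_ms: float):
    """Distinct-neuron count per bin (bins anchored at t = 0)."""
    n_bins = int(np.floor(spikes.duration / bin_ms)) + 1
    if spikes.n_spikes == 0:
        return np.zeros(n_bins, dtype=np.int64)
    bins = np.minimum((spikes.times / bin_ms).astype(np.int64), n_bins - 1)
    pairs = np.unique(np.stack([bins, spikes.ids.astype(np.int64)], axis=1), axis=0)
    counts = np.zeros(n_bins, dtype=np.int64)
    np.add.at(counts, pairs[:, 0], 1)
    return counts


def detect_pbs(spikes: SpikeData, n_total: int | None = None, bin_ms: float = 10.0,
               frac: float = 0.25) -> BurstCatalog:
    """Detect population bursts on a coarse binning of the raster.

    A bin is burst-active when the number of distinct neurons firing in
    it strictly exceeds ``frac * n_total``; runs of consecutive active
    bins merge into one PB whose peak is the centre of the
    maximal-count bin (first such bin on ties).
    """
    if n_total is None:
        n_total = spikes.n_neurons
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    counts = _binned_participation(spikes, bin_ms)
    active = counts > frac * n_total
    peaks, onsets, offsets, participants = [], [], [], []
    if active.any():
        padded = np.concatenate([[False], active, [False]])
        starts = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)[0]
        ends = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)[0]
        for s, e in zip(starts, ends):
            peak_bin = s + int(np.argmax(counts[s:e]))
            peaks.append((peak_bin + 0.5) * bin_ms)
            onsets.append(s * bin_ms)
            offsets.append(e * bin_ms)
            mask = (spikes.times >= s * bin_ms) & (spikes.times < e * bin_ms)
            participants.append(np.unique(spikes.ids[mask]))
    return BurstCatalog(
        pb_peak=np.array(peaks),
        pb_onset=np.array(onsets),
        pb_offset=np.array(offsets),
        pb_participants=participants,
        n_total=n_total,
        bin_ms=bin_ms,
    )


def refine_buildup(spikes: SpikeData, catalog: BurstCatalog, fine_bin_ms: float = 1.0,
                   peak_frac: float = 0.05, window_ms: float = 70.0):
    """Re-locate PB peaks at 1 ms resolution and extract build-up windows.

    For each PB the peak is the first fine bin (within the coarse event,
    extended by one coarse bin on each side) whose distinct-neuron count
    exceeds ``peak_frac * n_total``; the threshold crossing is then
    refined by linear interpolation between the counts of the previous
    and the qualifying bin.  The ``window_ms`` preceding the refined
    peak is the build-up window; each participant's first spike inside
    it is returned.  PBs with no qualifying fine bin are dropped with a
    warning.

    Returns ``(refined_catalog, windows)`` where ``windows`` is a list of
    dicts ``{neuron_id: first_spike_time_ms}`` (absolute times); the
    refined peak times are stored on the returned catalog.
    """
    if catalog.n_pb == 0:
        raise ValueError("catalog has no population bursts")
    thresh = peak_frac * catalog.n_total
    refined_peaks = []
    windows = []
    keep = []
    for k in range(catalog.n_pb):
        lo = catalog.pb_onset[k] - catalog.bin_ms
        hi = catalog.pb_offset[k] + catalog.bin_ms
        mask = (spikes.times >= lo) & (spikes.times < hi)
        t_loc = spikes.times[mask]
        id_loc = spikes.ids[mask]
        n_bins = int(np.ceil((hi - lo) / fine_bin_ms))
        fbins = np.minimum(((t_loc - lo) / fine_bin_ms).astype(np.int64), n_bins - 1)
        pairs = np.unique(np.stack([fbins, id_loc.astype(np.int64)], axis=1), axis=0) \
            if t_loc.size else np.empty((0, 2), dtype=np.int64)
        counts = np.zeros(n_bins, dtype=np.int64)
        if pairs.size:
            np.add.at(counts, pairs[:, 0], 1)
        above = np.nonzero(counts > thresh)[0]
        if above.size == 0:
            logger.warning("PB at %.1f ms has no %d ms bin above %.0f%% participation; dropped",
                           catalog.pb_peak[k], fine_bin_ms, 100 * peak_frac)
            continue
        b = above[0]
        # linear interpolation of the crossing between bins b-1 and b
        if b > 0 and counts[b] > counts[b - 1]:
            fracpos = (thresh - counts[b - 1]) / (counts[b] - counts[b - 1])
            fracpos = min(max(fracpos, 0.0), 1.0)
        else:
            fracpos = 0.0
        peak_t = lo + (b + fracpos) * fine_bin_ms
        refined_peaks.append(peak_t)
        keep.append(k)
        wmask = (spikes.times >= peak_t - window_ms) & (spikes.times < peak_t)
        first: dict[int, float] = {}
        for t, nid in zip(spikes.times[wmask], spikes.ids[wmask]):
            if int(nid) not in first:
                first[int(nid)] = float(t)
        windows.append(first)
    refined = BurstCatalog(
        pb_peak=catalog.pb_peak[keep],
        pb_onset=catalog.pb_onset[keep],
        pb_offset=catalog.pb_offset[keep],
        pb_participants=[catalog.pb_participants[k] for k in keep],
        ab_peak=catalog.ab_peak,
        n_total=catalog.n_total,
        bin_ms=catalog.bin_ms,
        pb_peak_refined=np.array(refined_peaks),
    )
    return refined, windows


def detect_abs(spikes: SpikeData, catalog: BurstCatalog, n_total: int | None = None,
               baseline_factor: float = 2.0, min_frac: float = 0.15,
               min_distance_ms: float = 50.0, isolation_bins: int = 3,
               isolation_frac: float = 0.5) -> np.ndarray:
    """Detect aborted bursts: sub-PB-threshold peaks of collective activity.

    An AB is a local maximum of the 10 ms binned distinct-neuron count
    that (a) exceeds ``baseline_factor`` times the median inter-burst
    bin count and involves at least ``min_frac`` of the population,
    (b) does not itself qualify as a PB and lies at least
    ``min_distance_ms`` away from every PB peak, and (c) is an
    isolated, event-like bump: the bins 2..``isolation_bins`` away on
    either side stay below ``isolation_frac`` of the peak (sustained
    elevated activity is not an aborted burst).  Returns the AB peak
    times and stores them on the catalog.
    """
    if n_total is None:
        n_total = catalog.n_total
    counts = _binned_participation(spikes, catalog.bin_ms)
    n_bins = counts.size
    centers = (np.arange(n_bins) + 0.5) * catalog.bin_ms
    in_pb = np.zeros(n_bins, dtype=bool)
    for s, e in zip(catalog.pb_onset, catalog.pb_offset):
        in_pb[int(s // catalog.bin_ms):int(np.ceil(e / catalog.bin_ms))] = True
    baseline = float(np.median(counts[~in_pb])) if (~in_pb).any() else 0.0
    thresh = max(baseline_factor * baseline, min_frac * n_total)

    ab_times = []
    for b in range(n_bins):
        c = counts[b]
        if c <= thresh:
            continue
        if in_pb[b] or c > 0.25 * n_total:
            continue
        left = counts[b - 1] if b > 0 else -1
        right = counts[b + 1] if b < n_bins - 1 else -1
        if not (c >= left and c > right):
            continue  # keep only the first bin of a plateau
        if catalog.n_pb and np.min(np.abs(catalog.pb_peak - centers[b])) < min_distance_ms:
            continue
        lo = counts[max(b - isolation_bins, 0):max(b - 1, 0)]
        hi = counts[b + 2:b + isolation_bins + 1]
        if ((lo.size and lo.max() > isolation_frac * c)
                or (hi.size and hi.max() > isolation_frac * c)):
            continue
        ab_times.append(centers[b])
    catalog.ab_peak = np.array(ab_times)
    return catalog.ab_peak


def event_participation(spikes: SpikeData, catalog: BurstCatalog,
                        buildup_ms: float = 70.0) -> np.ndarray:
    """Per-PB fraction of the population taking part in the whole event.

    The event window extends from ``buildup_ms`` before the peak (the
    build-up period, during which the early cells fire) to the PB
    offset, so the figure reflects everyone recruited by the
    synchronization, not only the neurons inside the suprathreshold
    bins.
    """
    fracs = np.empty(catalog.n_pb)
    for k in range(catalog.n_pb):
        lo = catalog.pb_peak[k] - buildup_ms
        hi = catalog.pb_offset[k]
        mask = (spikes.times >= lo) & (spikes.times < hi)
        fracs[k] = np.unique(spikes.ids[mask]).size / catalog.n_total
    return fracs


def phase_indicator(t_g: np.ndarray, delta_t: float) -> PhaseTrace:
    """Phase shift of each event against the control-rate expectation.

    ``phi_i = (t_g[i] - i * delta_t) / delta_t`` with events indexed
    from 1; negative drift means the events run faster than control.
    Times and ``delta_t`` must share units.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    t_g = np.asarray(t_g, dtype=float)
    idx = np.arange(1, t_g.size + 1)
    return PhaseTrace(phi=(t_g - idx * delta_t) / delta_t, delta_t=delta_t)


def rolling_mean_igi(t_g: np.ndarray, window_s: float = 60.0) -> np.ndarray:
    """Mean IGI in a forward window of ``window_s`` starting at each event (s).

    ``t_g`` are event times in seconds; events whose window extends past
    the last event contribute the mean of the intervals they do cover.
    """
    t_g = np.asarray(t_g, dtype=float)
    igi = np.diff(t_g)
    out = np.full(t_g.size, np.nan)
    for i in range(t_g.size - 1):
        in_win = (t_g[:-1] >= t_g[i]) & (t_g[:-1] < t_g[i] + window_s)
        if in_win.any():
            out[i] = igi[in_win].mean()
    return out


@dataclass
class IgiComparison:
    p_value: float
    significant: bool | None
    statistic: float
    undefined: bool = False


def compare_igi_epochs(igi_control, igi_test, alpha: float = 0.05) -> IgiComparison:
    """Two-sample Kolmogorov-Smirnov comparison of IGI distributions.

    With fewer than two events in either epoch no significance claim is
    made (``undefined`` result).
    """
    igi_control = np.asarray(igi_control, dtype=float)
    igi_test = np.asarray(igi_test, dtype=float)
    if igi_control.size < 2 or igi_test.size < 2:
        return IgiComparison(p_value=float("nan"), significant=None,
                             statistic=float("nan"), undefined=True)
    res = stats.ks_2samp(igi_control, igi_test)
    return IgiComparison(p_value=float(res.pvalue),
                         significant=bool(res.pvalue < alpha),
                         statistic=float(res.statistic))


def participation_similarity(catalog: BurstCatalog, n_total: int | None = None):
    """Pairwise cosine similarity of PB participation vectors and a 2-way split.

    Each PB is a binary participation vector over neurons; the pairwise
    cosine similarity matrix is clustered by average linkage (cosine
    distance) and cut into two groups.  Returns ``(similarity, labels,
    (n_high, n_low))`` where the high group has the larger mean
    participation.
    """
    if catalog.n_pb < 2:
        raise ValueError("need at least 2 PBs")
    if n_total is None:
        n_total = catalog.n_total
    mat = np.zeros((catalog.n_pb, n_total))
    for k, part in enumerate(catalog.pb_participants):
        mat[k, part] = 1.0
    norms = np.linalg.norm(mat, axis=1)
    norms[norms == 0] = 1.0
    sim = (mat @ mat.T) / np.outer(norms, norms)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    if np.allclose(dist, 0.0):
        labels = np.ones(catalog.n_pb, dtype=int)
    else:
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=2, criterion="maxclust")
    sizes = mat.sum(axis=1)
    if labels.max() == 1:
        n_high, n_low = catalog.n_pb, 0
    else:
        mean1 = sizes[labels == 1].mean()
        mean2 = sizes[labels == 2].mean()
        high = 1 if mean1 >= mean2 else 2
        n_high = int((labels == high).sum())
        n_low = catalog.n_pb - n_high
        labels = np.where(labels == high, 1, 2)
    return sim, labels, (n_high, n_low)
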