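"""Burst detection, phase indicator, IGI statistics, participation clustering."""

import numpy as np
import pytest

from burstclique.burstdetect import (
    compare_igi_epochs,
    detect_abs,
    detect_pbs,
    event_participation,
    participation_similarity,
    phase_indicator,
    refine_buildup,
    rolling_mean_igi,
)
from burstclique.dynamics import SpikeData


def raster(events, duration, n=100):
    """SpikeData from a list of (time, neuron_id)."""
    if events:
        t, i = zip(*sorted(events))
    else:
        t, i = (), ()
    return SpikeData(times=np.array(t, float), ids=np.array(i, np.int32),
                     duration=duration, n_neurons=n)


def volley(t0, neurons, spread=0.0):
    return [(t0 + spread * k / max(len(neurons), 1), nid)
            for k, nid in enumerate(neurons)]


class TestDetectPbs:
    def test_threshold_is_strict(self):
        sd26 = raster(volley(105.0, range(26)), 1000.0)
        sd25 = raster(volley(105.0, range(25)), 1000.0)
        assert detect_pbs(sd26).n_pb == 1
        assert detect_pbs(sd25).n_pb == 0

    def test_distinct_neuron_convention(self):
        # 26 spikes from 13 neurons do not qualify
        events = [(105.0 + 0.1 * k, k % 13) for k in range(26)]
        assert detect_pbs(raster(events, 1000.0)).n_pb == 0

    def test_empty_raster(self):
        cat = detect_pbs(raster([], 1000.0))
        assert cat.n_pb == 0 and cat.igi_s.size == 0

    def test_consecutive_bins_merge_into_one_event(self):
        events = volley(102.0, range(30)) + volley(112.0, range(30, 60))
        cat = detect_pbs(raster(events, 1000.0))
        assert cat.n_pb == 1
        assert cat.pb_width[0] == pytest.approx(20.0)
        assert cat.pb_participants[0].size == 60

    def test_igi_series_spans_peaks(self):
        events = volley(105.0, range(30)) + volley(905.0, range(30))
        cat = detect_pbs(raster(events, 1000.0))
        assert cat.igi_s.size == cat.n_pb - 1
        assert cat.igi_s.sum() == pytest.approx(
            (cat.pb_peak[-1] - cat.pb_peak[0]) / 1000.0)


class TestRefineBuildup:
    def test_peak_window_arithmetic(self):
        events = volley(1000.0, range(30), spread=0.5)
        cat = detect_pbs(raster(events, 2000.0))
        refined, windows = refine_buildup(raster(events, 2000.0), cat)
        peak = refined.pb_peak_refined[0]
        assert 1000.0 <= peak <= 1001.0
        assert all(peak - 70.0 <= t < peak for t in windows[0].values())

    def test_linear_interpolation_of_crossing(self):
        # fine-bin counts 3, 4, 6 with threshold 5 -> crossing halfway into bin 3
        events = []
        events += volley(100.0, range(3), spread=0.9)
        events += volley(101.0, range(3, 7), spread=0.9)
        events += volley(102.0, range(7, 13), spread=0.9)
        events += volley(103.0, range(13, 40), spread=0.9)  # make it a PB
        sd = raster(events, 500.0)
        cat = detect_pbs(sd)
        refined, _ = refine_buildup(sd, cat, peak_frac=0.05)
        # threshold 5 is crossed between the 4-count and 6-count bins
        assert refined.pb_peak_refined[0] == pytest.approx(102.5, abs=1e-9)

    def test_subthreshold_event_dropped_with_warning(self, caplog):
        # PB-qualifying at 10 ms binning but never >5 distinct in any 1 ms bin
        events = [(100.0 + 0.33 * k, k) for k in range(30)]
        sd = raster(events, 500.0)
        cat = detect_pbs(sd)
        assert cat.n_pb == 1
        with caplog.at_level("WARNING"):
            refined, _ = refine_buildup(sd, cat, peak_frac=0.05)
        assert refined.n_pb == 0 and "dropped" in caplog.text


class TestDetectAbs:
    def test_isolated_midsize_peak_is_ab(self):
        events = volley(105.0, range(30)) + volley(5105.0, range(30))
        events += volley(2505.0, range(16))          # isolated 16-neuron bump
        for b in range(0, 1000, 2):                  # sparse 2-neuron background
            events += [(b * 10.0 + 3.0, 90), (b * 10.0 + 7.0, 91)]
        sd = raster(events, 10_000.0)
        cat = detect_pbs(sd)
        abs_ = detect_abs(sd, cat)
        assert abs_.size == 1
        assert abs(abs_[0] - 2505.0) < 10.0

    def test_pb_is_never_ab(self):
        events = volley(105.0, range(30)) + volley(5105.0, range(40))
        sd = raster(events, 10_000.0)
        cat = detect_pbs(sd)
        assert detect_abs(sd, cat).size == 0

    def test_flat_activity_yields_no_ab(self):
        events = [(t, int(t) % 5) for t in np.arange(5.0, 9000.0, 11.0)]
        sd = raster(events, 10_000.0)
        cat = detect_pbs(sd)
        assert cat.n_pb == 0 and detect_abs(sd, cat).size == 0

    def test_sustained_elevation_rejected_by_isolation(self):
        events = []
        for b in range(40):  # 400 ms of sustained 18-neuron bins
            events += volley(3000.0 + b * 10.0 + 5.0, range(18))
        events += volley(105.0, range(30)) + volley(8105.0, range(30))
        sd = raster(events, 10_000.0)
        cat = detect_pbs(sd)
        assert detect_abs(sd, cat).size == 0


class TestPhaseIndicator:
    def test_on_schedule_events_have_zero_phase(self):
        t = np.arange(1, 11) * 2.0
        assert np.allclose(phase_indicator(t, 2.0).phi, 0.0)

    def test_worked_arithmetic(self):
        phi = phase_indicator([2.5, 5.0], 2.0).phi
        assert np.allclose(phi, [0.25, 0.5])

    def test_acceleration_gives_negative_drift(self):
        t = np.arange(1, 30) * 1.5   # faster than the 2 s control rate
        phi = phase_indicator(t, 2.0).phi
        assert phi[-1] < phi[0] < 0.0 or phi[-1] < 0.0

    def test_scale_invariance(self):
        t = np.array([2.5, 4.9, 7.8])
        a = phase_indicator(t, 2.0).phi
        b = phase_indicator(t * 3.0, 6.0).phi
        assert np.allclose(a, b)

    def test_invalid_delta_t(self):
        with pytest.raises(ValueError):
            phase_indicator([1.0], 0.0)


class TestIgiComparison:
    def test_identical_samples_not_significant(self):
        x = np.array([1.0, 1.2, 0.9, 1.4, 1.1])
        res = compare_igi_epochs(x, x)
        assert res.p_value == pytest.approx(1.0)
        assert res.significant is False

    def test_detects_rate_change(self):
        rng = np.random.default_rng(0)
        res = compare_igi_epochs(rng.exponential(1.0, 200),
                                 rng.exponential(0.2, 200))
        assert res.significant is True and res.p_value < 1e-6

    def test_degenerate_sample_flagged(self):
        res = compare_igi_epochs([1.0], np.ones(50))
        assert res.undefined and res.significant is None

    def test_rolling_mean_igi_constant_train(self):
        t = np.arange(50) * 2.0
        out = rolling_mean_igi(t, window_s=60.0)
        assert np.allclose(out[:-1][~np.isnan(out[:-1])], 2.0)


class TestParticipationSimilarity:
    def _catalog(self, participant_sets, n=100):
        events = []
        for k, p in enumerate(participant_sets):
            events += volley(105.0 + 1000.0 * k, p)
        sd = raster(events, 1000.0 * len(participant_sets) + 500.0, n)
        return detect_pbs(sd)

    def test_identical_sets_single_cluster(self):
        cat = self._catalog([range(40)] * 4)
        sim, labels, (nh, nl) = participation_similarity(cat)
        assert np.allclose(sim, 1.0)
        assert nh == 4 and nl == 0

    def test_disjoint_sets_split_perfectly(self):
        cat = self._catalog([range(40), range(40, 80)] * 3)
        sim, labels, (nh, nl) = participation_similarity(cat)
        assert nh == 3 and nl == 3
        assert len(set(labels[::2])) == 1 and len(set(labels[1::2])) == 1

    def test_planted_two_cluster_recovery(self):
        # high-participation events recruit ~80% of the population; the
        # low-participation events share a consistent 40-neuron core
        rng = np.random.default_rng(1)
        sets, truth = [], []
        for k in range(24):
            high = k % 2 == 0
            truth.append(high)
            base = np.zeros(100, bool)
            if high:
                base[rng.random(100) < 0.8] = True
            else:
                base[:40] = True
            flip = rng.random(100) < 0.10
            sets.append(np.nonzero(base ^ flip)[0])
        cat = self._catalog(sets)
        _, labels, _ = participation_similarity(cat)
        truth = np.array(truth)
        acc = max((labels[truth] == 1).mean() * 0.5 + (labels[~truth] == 2).mean() * 0.5,
                  (labels[truth] == 2).mean() * 0.5 + (labels[~truth] == 1).mean() * 0.5)
        assert acc > 0.9

    def test_event_participation_includes_buildup(self):
        events = volley(105.0, range(30))
        events += [(50.0 + k, 60 + k) for k in range(10)]  # early build-up cells
        sd = raster(events, 1000.0)
        cat = detect_pbs(sd)
        strict = cat.participation_fraction()[0]
        full = event_participation(sd, cat)[0]
        assert full > strict
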