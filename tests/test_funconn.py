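"""Functional connectivity: surrogates, correlogram, edge tests, degrees."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstclique.burstdetect import detect_pbs
from burstclique.dynamics import SpikeData
from burstclique.funconn import (
    assign_edge,
    binarize,
    build_functional_graph,
    cross_correlation,
    functional_degrees,
    lag_coincidences,
    make_surrogate,
)


def spike_data(per_neuron, duration, n=None):
    events = [(t, i) for i, ts in per_neuron.items() for t in ts]
    events.sort()
    t = np.array([e[0] for e in events], float)
    i = np.array([e[1] for e in events], np.int32)
    n = n if n is not None else (max(per_neuron) + 1)
    return SpikeData(times=t, ids=i, duration=duration, n_neurons=n)


class TestSurrogates:
    def test_degree_mode_keeps_one_spike_per_burst(self):
        sd = spike_data({0: [0.0, 10.0, 20.0, 100.0]}, 200.0)
        out = make_surrogate(sd, "degree")
        assert np.allclose(out[0], [0.0, 100.0])

    def test_silent_neuron_has_empty_list(self):
        sd = spike_data({0: [5.0], 1: []}, 100.0, n=2)
        out = make_surrogate(sd, "degree")
        assert out[1].size == 0

    def test_buildup_mode_first_spike_in_window(self):
        burst = [(500.0 + 0.1 * k, k) for k in range(30)]
        pre = {0: [420.0, 450.0, 480.0], 1: [300.0]}
        sd = spike_data({**{k: [500.0 + 0.1 * k] for k in range(30)},
                         0: [420.0, 450.0, 480.0, 500.0],
                         1: [300.0]}, 1000.0, n=31)
        cat = detect_pbs(sd, n_total=31)
        assert cat.n_pb == 1
        out = make_surrogate(sd, "buildup", cat)
        peak = cat.pb_peak[0]
        assert out[0].size == 1 and peak - 70 <= out[0][0] < peak
        assert out[0][0] == 450.0 or out[0][0] == 480.0  # first spike in window
        assert out[1].size == 0  # fired only long before the burst

    def test_interburst_mode_excludes_burst_spans(self):
        events = {k: [105.0] for k in range(30)}
        events[0] = [50.0, 105.0, 300.0]
        sd = spike_data(events, 1000.0)
        cat = detect_pbs(sd)
        out = make_surrogate(sd, "interburst", sd and cat)
        assert np.allclose(out[0], [50.0, 300.0])

    def test_missing_catalog_rejected(self):
        sd = spike_data({0: [1.0]}, 10.0)
        with pytest.raises(ValueError):
            make_surrogate(sd, "buildup")


class TestCrossCorrelation:
    def test_identical_single_event(self):
        a = binarize([50.0], 200.0)
        lags, c = cross_correlation(a, a, max_lag=20)
        assert c[lags == 0] == pytest.approx(1.0)
        assert c[lags != 0].max() == 0.0

    def test_known_lag_peak_and_value(self):
        a = binarize([7.0], 50.0)
        b = binarize([5.0], 50.0)
        lags, c = cross_correlation(a, b, max_lag=10)
        assert c[lags == 2] == pytest.approx(1.0)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        a = (rng.random(2000) < 0.05).astype(np.int8)
        b = (rng.random(2000) < 0.05).astype(np.int8)
        _, c = cross_correlation(a, b, max_lag=100)
        assert np.all((0.0 <= c) & (c <= 1.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_under_argument_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random(500) < 0.08).astype(np.int8)
        b = (rng.random(500) < 0.08).astype(np.int8)
        if a.sum() == 0 or b.sum() == 0:
            return
        lags, cab = cross_correlation(a, b, max_lag=50)
        _, cba = cross_correlation(b, a, max_lag=50)
        assert np.allclose(cab, cba[::-1])

    def test_lag_coincidences_equals_dense_correlogram(self):
        rng = np.random.default_rng(3)
        ta = np.sort(rng.uniform(0, 3000, 40))
        tb = np.sort(rng.uniform(0, 3000, 50))
        sample = lag_coincidences(ta, tb, max_lag=200)
        a = binarize(ta, 3000.0)
        b = binarize(tb, 3000.0)
        lags, c = cross_correlation(a, b, max_lag=200)
        dense = np.repeat(lags, np.round(c * min(a.sum(), b.sum())).astype(int))
        assert np.array_equal(np.sort(sample), np.sort(dense))


class TestEdgeAssignment:
    def test_flat_correlogram_gives_no_edge(self):
        rng = np.random.default_rng(0)
        sample = rng.integers(-500, 501, 400)
        assert assign_edge(sample) is None

    def test_synchronous_gaussian_gives_no_edge(self):
        rng = np.random.default_rng(1)
        sample = np.round(rng.normal(0, 5, 400)).astype(int)
        assert assign_edge(sample) is None

    def test_sharp_positive_lag_gives_directed_edge(self):
        rng = np.random.default_rng(2)
        sample = np.round(rng.normal(8, 1, 100)).astype(int)
        res = assign_edge(sample)
        assert res is not None
        direction, tau, _ = res
        assert direction == 1 and 6 <= tau <= 10

    def test_false_edge_rate_on_independent_poisson(self):
        rng = np.random.default_rng(10)
        n_pairs, false = 60, 0
        for _ in range(n_pairs):
            ta = np.sort(rng.uniform(0, 20_000, 60))
            tb = np.sort(rng.uniform(0, 20_000, 60))
            sample = lag_coincidences(ta, tb, max_lag=500)
            if sample.size >= 2 and assign_edge(sample) is not None:
                false += 1
        # alpha = 0.05 joint test, allow 3-sigma binomial slack
        assert false <= n_pairs * 0.05 + 3 * np.sqrt(n_pairs * 0.05 * 0.95)


class TestGraphAndDegrees:
    def _chain_timestamps(self, lag_ms=8.0, n_events=120, jitter=0.8, seed=0):
        rng = np.random.default_rng(seed)
        base = np.arange(n_events) * 700.0 + 100.0
        return {
            0: base + rng.normal(0, jitter, n_events),
            1: base + lag_ms + rng.normal(0, jitter, n_events),
            2: base + 2 * lag_ms + rng.normal(0, jitter, n_events),
        }

    def test_planted_chain_recovered_with_direction(self):
        ts = self._chain_timestamps()
        g = build_functional_graph(ts, duration_ms=100_000.0, max_lag=100)
        pairs = {(s, d) for s, d, _t, _c in g.edges}
        assert (0, 1) in pairs and (1, 2) in pairs and (0, 2) in pairs
        assert not any(s > d for s, d in pairs)
        d_out, d_in, _ = functional_degrees(g)
        assert d_out[0] == pytest.approx(100.0)
        assert d_in[0] == 0.0

    def test_star_driver_degrees(self):
        rng = np.random.default_rng(5)
        base = np.arange(100) * 500.0 + 50.0
        ts = {0: base + rng.normal(0, 0.5, 100)}
        for k in range(1, 5):
            ts[k] = base + 6.0 + k + rng.normal(0, 0.5, 100)
        g = build_functional_graph(ts, duration_ms=60_000.0, max_lag=60)
        d_out, d_in, hubs = functional_degrees(g)
        assert d_out[0] == pytest.approx(100.0)
        assert 0 in hubs
        assert np.all(d_in[1:] > 0)

    def test_empty_graph_degrees_zero(self):
        g = build_functional_graph({0: [], 1: []}, duration_ms=1000.0)
        d_out, d_in, hubs = functional_degrees(g, 2)
        assert np.all(d_out == 0) and np.all(d_in == 0) and hubs.size == 0
        assert g.silent == [0, 1]

    def test_unordered_pair_single_edge(self):
        ts = self._chain_timestamps()
        g = build_functional_graph(ts, duration_ms=100_000.0, max_lag=100)
        seen = {frozenset((s, d)) for s, d, _t, _c in g.edges}
        assert len(seen) == len(g.edges)
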