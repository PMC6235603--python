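"""Fixed-step Runge-Kutta cross-validation integrator.

An intentionally naive integrator for the same network equations,
used to cross-check the event-driven simulation on small motifs: it
advances the coupled ODEs with classical RK4 at a fixed step
(default 1e-3 ms), locates threshold crossings by bisecting the step,
and applies the spike rules at the located crossing time.  It shares
no code path with the event-driven kernel beyond the model
definition, so agreement between the two is a meaningful check.
Intended for networks of a handful of neurons over ~1 s horizons;
it is orders of magnitude slower than the event-driven map.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import TAU_M, V_R, V_TH
from .netgen import NetworkRealization


@njit(cache=True)
def _deriv(w, dw, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti, tr, tf, uu0,
           hasf, tau):
    for i in range(n):
        if not alive[i]:
            dw[i] = 0.0
            continue
        isyn = 0.0
        for k in range(in_ptr[i], in_ptr[i + 1]):
            e = in_idx[k]
            isyn += gnorm[e] * w[n + e]
        dw[i] = (-w[i] + cur_i[i] + isyn) / tau
    for e in range(E):
        y = w[n + e]
        z = w[n + E + e]
        dw[n + e] = -y / ti[e]
        dw[n + E + e] = y / ti[e] - z / tr[e]
        if hasf[e]:
            dw[n + 2 * E + e] = -(w[n + 2 * E + e] - uu0[e]) / tf[e]
        else:
            dw[n + 2 * E + e] = 0.0


@njit(cache=True)
def _rk4_step(w, h, out, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti, tr, tf,
              uu0, hasf, tau, k1, k2, k3, k4, tmp):
    _deriv(w, k1, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti, tr, tf, uu0, hasf, tau)
    for q in range(w.size):
        tmp[q] = w[q] + 0.5 * h * k1[q]
    _deriv(tmp, k2, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti, tr, tf, uu0, hasf, tau)
    for q in range(w.size):
        tmp[q] = w[q] + 0.5 * h * k2[q]
    _deriv(tmp, k3, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti, tr, tf, uu0, hasf, tau)
    for q in range(w.size):
        tmp[q] = w[q] + h * k3[q]
    _deriv(tmp, k4, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti, tr, tf, uu0, hasf, tau)
    for q in range(w.size):
        out[q] = w[q] + (h / 6.0) * (k1[q] + 2.0 * k2[q] + 2.0 * k3[q] + k4[q])


@njit(cache=True)
def _run_reference(n, E, cur_i, alive, in_ptr, in_idx, out_ptr, out_idx, epost,
                   gnorm, ti, tr, tf, uu0, hasf, w0, duration, dt, tau, vr, vth,
                   max_spikes):
    w = w0.copy()
    wn = np.empty_like(w)
    k1 = np.empty_like(w)
    k2 = np.empty_like(w)
    k3 = np.empty_like(w)
    k4 = np.empty_like(w)
    tmp = np.empty_like(w)
    spike_t = np.empty(max_spikes)
    spike_id = np.empty(max_spikes, dtype=np.int32)
    n_spikes = 0
    t = 0.0
    while t < duration - 1e-12:
        h = min(dt, duration - t)
        _rk4_step(w, h, wn, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti, tr,
                  tf, uu0, hasf, tau, k1, k2, k3, k4, tmp)
        crossed = False
        for i in range(n):
            if alive[i] and wn[i] >= vth:
                crossed = True
                break
        if not crossed:
            for q in range(w.size):
                w[q] = wn[q]
            t += h
            continue
        # bisect the step length down to the earliest crossing
        lo = 0.0
        hi = h
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            _rk4_step(w, mid, wn, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti,
                      tr, tf, uu0, hasf, tau, k1, k2, k3, k4, tmp)
            any_cross = False
            for i in range(n):
                if alive[i] and wn[i] >= vth:
                    any_cross = True
                    break
            if any_cross:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-12:
                break
        _rk4_step(w, hi, wn, n, E, cur_i, alive, in_ptr, in_idx, gnorm, ti, tr,
                  tf, uu0, hasf, tau, k1, k2, k3, k4, tmp)
        for q in range(w.size):
            w[q] = wn[q]
        t += hi
        for j in range(n):
            if alive[j] and w[j] >= vth:
                if n_spikes >= max_spikes:
                    return spike_t, spike_id, n_spikes, w
                spike_t[n_spikes] = t
                spike_id[n_spikes] = j
                n_spikes += 1
                w[j] = vr
                for k in range(out_ptr[j], out_ptr[j + 1]):
                    e = out_idx[k]
                    if hasf[e]:
                        w[n + 2 * E + e] += uu0[e] * (1.0 - w[n + 2 * E + e])
                    x = 1.0 - w[n + e] - w[n + E + e]
                    w[n + e] += w[n + 2 * E + e] * x
    return spike_t, spike_id, n_spikes, w


def reference_simulate(
    network: NetworkRealization,
    duration_ms: float,
    v_init: np.ndarray,
    dt_ms: float = 1e-3,
    extra_current: np.ndarray | None = None,
    deleted=(),
):
    """Integrate the network with fixed-step RK4; returns (times, ids, final_state).

    ``v_init`` gives the initial membrane potentials; synapses start
    fully recovered (X=1) with u=U, matching the event-driven default.
    """
    n = network.n
    E = network.n_edges
    epost = network.edge_post.astype(np.int64)
    epre = network.edge_pre.astype(np.int64)
    k_in = network.in_degree
    gnorm = network.coupling / np.maximum(k_in[epost], 1)
    ti = network.decay
    tr = network.recovery
    tf = np.where(np.isnan(network.facilitation_tau), 1.0, network.facilitation_tau)
    hasf = (~np.isnan(network.facilitation_tau)).astype(np.uint8)
    uu0 = network.baseline_u

    def csr(key):
        order = np.argsort(key, kind="stable").astype(np.int64)
        ptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(ptr, key + 1, 1)
        np.cumsum(ptr, out=ptr)
        return ptr, order

    in_ptr, in_idx = csr(epost)
    out_ptr, out_idx = csr(epre)

    cur_i = network.excitability.astype(float).copy()
    if extra_current is not None:
        cur_i = cur_i + extra_current
    alive = np.ones(n, dtype=np.uint8)
    for d in deleted:
        alive[d] = 0

    w0 = np.empty(n + 3 * E)
    w0[:n] = v_init
    w0[n:n + E] = 0.0          # Y
    w0[n + E:n + 2 * E] = 0.0  # Z
    w0[n + 2 * E:] = uu0       # u

    max_spikes = max(10_000, int(n * duration_ms))
    spike_t, spike_id, n_spikes, w = _run_reference(
        n, E, cur_i, alive, in_ptr, in_idx, out_ptr, out_idx, epost,
        gnorm, ti, tr, tf, uu0, hasf, w0, float(duration_ms), float(dt_ms),
        TAU_M, V_R, V_TH, max_spikes,
    )
    return spike_t[:n_spikes], spike_id[:n_spikes], w
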