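"""Numba kernels for the event-driven simulation.

Between spikes every state variable has a closed form:

* synaptic active fraction     Y(t) = Y0 exp(-t/T_I)
* inactive fraction            Z(t) solves Zdot = Y/T_I - Z/T_R (two-exponential)
* recovered fraction           X = 1 - Y - Z (identity, conserved exactly)
* facilitation                 u(t) = U + (u0 - U) exp(-t/T_F)
* membrane potential           V(t) = I + sum_k b_k exp(-t/T_I_k) + c exp(-t/tau_m)

so the simulation advances exactly from one threshold crossing to the
next.  The crossing time of the sum-of-exponentials V(t) has no closed
form; it is located by a marching bracket with a rigorous interval
upper bound (each exponential term is monotone, so its maximum on an
interval sits at one end), subdivision when the bound is inconclusive,
and bisection refinement to 1e-10 ms.  The bound makes the search
guaranteed: an interval is discarded only when V provably stays below
threshold on it.
"""

import numpy as np
from numba import njit

#: refinement tolerance for threshold crossings, ms
ROOT_TOL = 1e-10
#: smallest subdivided interval retained in the bump search, ms
MIN_INTERVAL = 1e-9

_STATUS_OK = 0
_STATUS_SPIKE_OVERFLOW = 1


@njit(cache=True, inline="always")
def _f_eval(d, k0, c, tau, bs, ss, m):
    """V(d) - V_th as a function of the delay d from the reference time."""
    s = k0 + c * np.exp(-d / tau)
    for q in range(m):
        s += bs[q] * np.exp(-d / ss[q])
    return s


@njit(cache=True, inline="always")
def _ub_eval(d1, d2, k0, c, tau, bs, ss, m):
    """Rigorous upper bound of f on [d1, d2] (each term maximal at one end)."""
    if c > 0.0:
        s = k0 + c * np.exp(-d1 / tau)
    else:
        s = k0 + c * np.exp(-d2 / tau)
    for q in range(m):
        if bs[q] > 0.0:
            s += bs[q] * np.exp(-d1 / ss[q])
        else:
            s += bs[q] * np.exp(-d2 / ss[q])
    return s


@njit(cache=True)
def _refine(a, b, k0, c, tau, bs, ss, m):
    """Bisect the bracket [a, b] (f(a) < 0 <= f(b)) down to ROOT_TOL; returns b."""
    for _ in range(80):
        if b - a <= ROOT_TOL:
            break
        x = 0.5 * (a + b)
        if _f_eval(x, k0, c, tau, bs, ss, m) >= 0.0:
            b = x
        else:
            a = x
    return b


@njit(cache=True)
def _scan_interval(d1, f1, d2, f2, k0, c, tau, bs, ss, m):
    """Left-first search for an interior crossing when the bound is inconclusive.

    Both endpoints are below threshold; subdivides until either a
    crossing is bracketed (returns it) or every sub-interval is
    rigorously excluded.
    """
    sd1 = np.empty(130)
    sf1 = np.empty(130)
    sd2 = np.empty(130)
    sp = 0
    sd1[0] = d1
    sf1[0] = f1
    sd2[0] = d2
    sp = 1
    while sp > 0:
        sp -= 1
        a = sd1[sp]
        fa = sf1[sp]
        b = sd2[sp]
        if b - a < MIN_INTERVAL:
            continue
        if _ub_eval(a, b, k0, c, tau, bs, ss, m) < 0.0:
            continue
        mid = 0.5 * (a + b)
        fm = _f_eval(mid, k0, c, tau, bs, ss, m)
        if fm >= 0.0:
            return True, _refine(a, mid, k0, c, tau, bs, ss, m)
        if sp > 126:
            # stack exhaustion cannot happen for the interval widths used
            # (depth <= ~45 before MIN_INTERVAL); keep the guard anyway
            continue
        sd1[sp] = mid
        sf1[sp] = fm
        sd2[sp] = b
        sp += 1
        sd1[sp] = a
        sf1[sp] = fa
        sd2[sp] = mid
        sp += 1
    return False, 0.0


@njit(cache=True)
def _earliest_crossing(k0, c, tau, bs, ss, m, h0, hmax):
    """First zero of f(d) for d > 0 given f(0) < 0, or inf if none exists."""
    d1 = 0.0
    f1 = k0 + c
    for q in range(m):
        f1 += bs[q]
    h = h0
    while True:
        d2 = d1 + h
        if _ub_eval(d1, d2, k0, c, tau, bs, ss, m) < 0.0:
            # excluded on [d1, d2]; can the tail d > d2 ever cross?
            tail = k0
            if c > 0.0:
                tail += c * np.exp(-d2 / tau)
            for q in range(m):
                if bs[q] > 0.0:
                    tail += bs[q] * np.exp(-d2 / ss[q])
            if tail < 1e-14:
                return np.inf
            d1 = d2
            f1 = _f_eval(d1, k0, c, tau, bs, ss, m)
        else:
            f2 = _f_eval(d2, k0, c, tau, bs, ss, m)
            if f2 >= 0.0:
                return _refine(d1, d2, k0, c, tau, bs, ss, m)
            found, root = _scan_interval(d1, f1, d2, f2, k0, c, tau, bs, ss, m)
            if found:
                return root
            d1 = d2
            f1 = f2
        h = min(h * 1.4, hmax)


@njit(cache=True)
def _predict(i, tnow, alive, cur_i, V, in_ptr, in_idx, Y, tE, ti, gnorm,
             tau, vth, ws_b, ws_s):
    """Absolute time of neuron i's next threshold crossing (requires tV[i] == tnow)."""
    if not alive[i]:
        return np.inf
    base = cur_i[i]
    m = 0
    smin = tau
    for k in range(in_ptr[i], in_ptr[i + 1]):
        e = in_idx[k]
        ye = Y[e] * np.exp(-(tnow - tE[e]) / ti[e])
        a = gnorm[e] * ye
        if -1e-14 < a < 1e-14:
            continue
        ws_b[m] = a * ti[e] / (ti[e] - tau)
        ws_s[m] = ti[e]
        if ti[e] < smin:
            smin = ti[e]
        m += 1
    c = V[i] - base
    for q in range(m):
        c -= ws_b[q]
    if V[i] >= vth:
        return tnow
    k0 = base - vth
    d = _earliest_crossing(k0, c, tau, ws_b, ws_s, m, 0.25 * smin, 0.5 * tau)
    return tnow + d


@njit(cache=True)
def run_event_driven(
    ib, in_ptr, in_idx, out_ptr, out_idx,
    epost, gnorm, ti, tr, tf, uu0, hasf,
    v_init, u_init,
    t_end, burn_in,
    sched_t, sched_kind, sched_nrn, sched_val,
    delta, rng_seed,
    mon_out_ptr, mon_out_edges, mon_in_ptr, mon_in_edges,
    sample_dt,
    max_spikes,
    tau, vr, vth,
):
    """Event-driven simulation of the full network.

    Schedule entries (sorted by time): kind 0 adds ``sched_val`` to the
    neuron's drive, kind 1 removes it, kind 2 deletes the neuron
    (it stops integrating and firing).  Spikes are recorded over the
    whole run; the wrapper discards the burn-in.  Monitoring samples
    the mean recovered fraction X over the listed efferent/afferent
    edge groups every ``sample_dt`` ms from ``burn_in`` onward.
    """
    n = ib.size
    E = gnorm.size
    np.random.seed(rng_seed)

    V = v_init.copy()
    tV = np.zeros(n)
    Y = np.zeros(E)
    Z = np.zeros(E)
    u = u_init.copy()
    tE = np.zeros(E)
    cur_i = ib.copy()
    alive = np.ones(n, dtype=np.uint8)
    next_t = np.empty(n)
    ws_b = np.empty(n + E)
    ws_s = np.empty(n + E)

    spike_t = np.empty(max_spikes)
    spike_id = np.empty(max_spikes, dtype=np.int32)
    n_spikes = 0

    n_mon = mon_out_ptr.size - 1
    if n_mon > 0 and sample_dt > 0.0:
        n_samp_max = int((t_end - burn_in) / sample_dt) + 2
    else:
        n_samp_max = 0
    xout = np.zeros((n_samp_max, n_mon))
    xin = np.zeros((n_samp_max, n_mon))
    samp_t = np.zeros(n_samp_max)
    n_samp = 0
    next_sample = burn_in if n_samp_max > 0 else np.inf

    for i in range(n):
        next_t[i] = _predict(i, 0.0, alive, cur_i, V, in_ptr, in_idx, Y, tE,
                             ti, gnorm, tau, vth, ws_b, ws_s)

    sp = 0
    n_sched = sched_t.size

    while True:
        # earliest threshold crossing, ties broken by neuron index
        j = -1
        tn = np.inf
        for i in range(n):
            if next_t[i] < tn:
                tn = next_t[i]
                j = i
        t_sched = sched_t[sp] if sp < n_sched else np.inf
        tmin = tn
        if t_sched < tmin:
            tmin = t_sched
        if next_sample < tmin:
            tmin = next_sample
        if tmin >= t_end:
            break

        if next_sample <= tn and next_sample <= t_sched:
            # read-only sampling of synaptic resources at next_sample
            ts = next_sample
            for mi in range(n_mon):
                for block in range(2):
                    if block == 0:
                        lo = mon_out_ptr[mi]
                        hi = mon_out_ptr[mi + 1]
                        edges = mon_out_edges
                    else:
                        lo = mon_in_ptr[mi]
                        hi = mon_in_ptr[mi + 1]
                        edges = mon_in_edges
                    acc = 0.0
                    cnt = hi - lo
                    for k in range(lo, hi):
                        e = edges[k]
                        dt = ts - tE[e]
                        y0 = Y[e]
                        z0 = Z[e]
                        ey = np.exp(-dt / ti[e])
                        er = np.exp(-dt / tr[e])
                        diff = ti[e] - tr[e]
                        if abs(diff) > 1e-9:
                            A = y0 * tr[e] / diff
                            zt = (z0 - A) * er + A * ey
                        else:
                            zt = (z0 + y0 * dt / ti[e]) * er
                        acc += 1.0 - y0 * ey - zt
                    val = acc / cnt if cnt > 0 else np.nan
                    if block == 0:
                        xout[n_samp, mi] = val
                    else:
                        xin[n_samp, mi] = val
            samp_t[n_samp] = ts - burn_in
            n_samp += 1
            next_sample = burn_in + n_samp * sample_dt
            continue

        if t_sched <= tn:
            nrn = sched_nrn[sp]
            kind = sched_kind[sp]
            # advance the neuron's membrane state to the schedule time
            dtv = t_sched - tV[nrn]
            if dtv > 0.0:
                base = cur_i[nrn]
                sumb = 0.0
                sumbe = 0.0
                for k in range(in_ptr[nrn], in_ptr[nrn + 1]):
                    e = in_idx[k]
                    ye = Y[e] * np.exp(-(tV[nrn] - tE[e]) / ti[e])
                    a = gnorm[e] * ye
                    if a != 0.0:
                        b = a * ti[e] / (ti[e] - tau)
                        sumb += b
                        sumbe += b * np.exp(-dtv / ti[e])
                V[nrn] = base + sumbe + (V[nrn] - base - sumb) * np.exp(-dtv / tau)
            tV[nrn] = t_sched
            if kind == 0:
                cur_i[nrn] += sched_val[sp]
            elif kind == 1:
                cur_i[nrn] -= sched_val[sp]
            else:
                alive[nrn] = 0
            next_t[nrn] = _predict(nrn, t_sched, alive, cur_i, V, in_ptr, in_idx,
                                   Y, tE, ti, gnorm, tau, vth, ws_b, ws_s)
            sp += 1
            continue

        # ---- spike of neuron j at time tn ----
        if n_spikes >= max_spikes:
            return (spike_t, spike_id, n_spikes, xout, xin, samp_t, n_samp,
                    _STATUS_SPIKE_OVERFLOW)
        spike_t[n_spikes] = tn
        spike_id[n_spikes] = j
        n_spikes += 1

        if delta > 0.0:
            V[j] = vr + delta * (2.0 * np.random.random() - 1.0)
        else:
            V[j] = vr
        tV[j] = tn

        for k in range(out_ptr[j], out_ptr[j + 1]):
            e = out_idx[k]
            i = epost[e]
            if alive[i]:
                # advance the postsynaptic membrane to tn with the OLD drive
                dtv = tn - tV[i]
                if dtv > 0.0:
                    base = cur_i[i]
                    sumb = 0.0
                    sumbe = 0.0
                    for kk in range(in_ptr[i], in_ptr[i + 1]):
                        ee = in_idx[kk]
                        ye = Y[ee] * np.exp(-(tV[i] - tE[ee]) / ti[ee])
                        a = gnorm[ee] * ye
                        if a != 0.0:
                            b = a * ti[ee] / (ti[ee] - tau)
                            sumb += b
                            sumbe += b * np.exp(-dtv / ti[ee])
                    V[i] = base + sumbe + (V[i] - base - sumb) * np.exp(-dtv / tau)
                tV[i] = tn
            # advance the synapse to tn, then apply the spike
            dte = tn - tE[e]
            if dte > 0.0:
                y0 = Y[e]
                z0 = Z[e]
                ey = np.exp(-dte / ti[e])
                er = np.exp(-dte / tr[e])
                diff = ti[e] - tr[e]
                if abs(diff) > 1e-9:
                    A = y0 * tr[e] / diff
                    Z[e] = (z0 - A) * er + A * ey
                else:
                    Z[e] = (z0 + y0 * dte / ti[e]) * er
                Y[e] = y0 * ey
                if hasf[e]:
                    u[e] = uu0[e] + (u[e] - uu0[e]) * np.exp(-dte / tf[e])
            tE[e] = tn
            if hasf[e]:
                # facilitation: update u, then use it for the release
                u[e] = u[e] + uu0[e] * (1.0 - u[e])
            rel = u[e] * (1.0 - Y[e] - Z[e])
            Y[e] += rel
            if alive[i]:
                next_t[i] = _predict(i, tn, alive, cur_i, V, in_ptr, in_idx,
                                     Y, tE, ti, gnorm, tau, vth, ws_b, ws_s)
        next_t[j] = _predict(j, tn, alive, cur_i, V, in_ptr, in_idx,
                             Y, tE, ti, gnorm, tau, vth, ws_b, ws_s)

    return spike_t, spike_id, n_spikes, xout, xin, samp_t, n_samp, _STATUS_OK
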