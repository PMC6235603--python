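"""End-to-end pipeline: build, simulate, detect, infer, perturb, classify.

Every stage writes its artifact under an output directory and is
recorded in a JSON run manifest; all randomness derives from one root
seed, so a rerun of the same manifest (without reset noise) is
bit-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .burstdetect import detect_abs, detect_pbs
from .config import NetworkConfig
from .dynamics import simulate
from .funconn import build_functional_graph, functional_degrees, make_surrogate
from .netgen import build_network
from .perturb import (
    WINDOW_S,
    baseline_variability,
    classify_drivers,
    snd_experiment,
    sweep_sns,
)

__all__ = ["run_pipeline", "control_statistics", "DEFAULT_SNS_GRID"]


def control_statistics(
    correlated: bool = True,
    seed: int = 0,
    n_realizations: int = 5,
    max_attempts: int = 12,
    window_s: float = WINDOW_S,
    burn_in_s: float = 10.0,
    min_pbs: int = 10,
) -> dict:
    """Pooled control-condition burst statistics over bursting realizations.

    Builds realizations from consecutive seeds, simulates one window
    each, and pools inter-burst intervals, burst widths, aborted-burst
    counts and event participation over the realizations that burst
    (at least ``min_pbs`` population bursts; like the biological
    preparations, a fraction of realizations shows no usable bursting
    and is excluded).  Returns a dict of pooled summary numbers.
    """
    from .burstdetect import detect_abs, detect_pbs, event_participation
    from .dynamics import simulate as _simulate

    igis, widths, parts = [], [], []
    n_pb_total = n_ab_total = 0
    used, skipped = [], []
    for k in range(max_attempts):
        if len(used) >= n_realizations:
            break
        net_seed = seed + k
        cfg = NetworkConfig(seed=net_seed, correlated=correlated)
        net = build_network(cfg)
        sim_seed = (seed * 100_003 + 1000 + k) % (2**31)
        spikes = _simulate(net, window_s * 1000.0, seed=sim_seed,
                           burn_in_ms=burn_in_s * 1000.0)
        catalog = detect_pbs(spikes)
        if catalog.n_pb < min_pbs:
            skipped.append(net_seed)
            continue
        detect_abs(spikes, catalog)
        igis.append(catalog.igi_s)
        widths.append(catalog.pb_width)
        parts.append(event_participation(spikes, catalog))
        n_pb_total += catalog.n_pb
        n_ab_total += catalog.n_ab
        used.append(net_seed)
    igi = np.concatenate(igis) if igis else np.empty(0)
    width = np.concatenate(widths) if widths else np.empty(0)
    part = np.concatenate(parts) if parts else np.empty(0)
    return {
        "correlated": correlated,
        "n_bursting": len(used),
        "seeds_used": used,
        "seeds_skipped": skipped,
        "n_pb": int(n_pb_total),
        "n_ab": int(n_ab_total),
        "igi_mean_s": float(igi.mean()) if igi.size else float("nan"),
        "igi_sd_s": float(igi.std(ddof=1)) if igi.size > 1 else float("nan"),
        "width_mean_ms": float(width.mean()) if width.size else float("nan"),
        "ab_pb_percent": 100.0 * n_ab_total / n_pb_total if n_pb_total else float("nan"),
        "participation_percent": 100.0 * float(part.mean()) if part.size else float("nan"),
    }

#: coarse default stimulation grid (mV); the fine protocol steps by 0.015 mV
DEFAULT_SNS_GRID = tuple(np.round(np.arange(14.55, 18.0, 0.35), 3))


def run_pipeline(
    config: NetworkConfig | None = None,
    out_dir: str | Path = "runs",
    seed: int = 0,
    window_s: float = WINDOW_S,
    burn_in_s: float = 10.0,
    n_baseline_runs: int = 20,
    sns_grid=DEFAULT_SNS_GRID,
    sns_neurons=None,
    snd_neurons=None,
) -> dict:
    """Run every stage and return the manifest (also written to disk).

    ``sns_neurons`` / ``snd_neurons`` restrict the stimulation sweeps
    and deletions to subsets of neurons (default: all).
    """
    t0 = time.time()
    cfg = config if config is not None else NetworkConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": asdict(cfg),
        "window_s": window_s,
        "burn_in_s": burn_in_s,
        "artifacts": {},
        "stages": {},
    }

    def note(stage, **kw):
        manifest["stages"][stage] = {"wall_s": round(time.time() - t0, 2), **kw}

    # 1. network
    net = build_network(cfg, seed=int(rng.integers(2**31)))
    net.to_files(out / "neurons.tsv", out / "edges.tsv")
    manifest["artifacts"]["neurons"] = str(out / "neurons.tsv")
    manifest["artifacts"]["edges"] = str(out / "edges.tsv")
    note("netgen", n=net.n, n_edges=net.n_edges)

    # 2. control simulation
    sim_seed = int(rng.integers(2**31))
    spikes = simulate(net, window_s * 1000.0, seed=sim_seed,
                      burn_in_ms=burn_in_s * 1000.0)
    spikes.to_tsv(out / "spikes_control.tsv")
    manifest["artifacts"]["spikes_control"] = str(out / "spikes_control.tsv")
    note("simulate", seed=sim_seed, n_spikes=int(spikes.n_spikes))

    # 3. burst detection
    catalog = detect_pbs(spikes)
    detect_abs(spikes, catalog)
    catalog.to_tsv(out / "bursts.tsv")
    summary = catalog.summary()
    (out / "burst_summary.json").write_text(json.dumps(summary, indent=2))
    manifest["artifacts"]["bursts"] = str(out / "bursts.tsv")
    note("burstdetect", **summary)

    # 4. functional connectivity (one-spike-per-burst surrogate)
    surr = make_surrogate(spikes, "degree")
    graph = build_functional_graph(surr, spikes.duration)
    graph.to_tsv(out / "funconn_edges.tsv")
    d_out, d_in, fc_hubs = functional_degrees(graph)
    np.savetxt(out / "funconn_degrees.tsv",
               np.column_stack([np.arange(net.n), d_out, d_in]),
               header="neuron\td_out_pct\td_in_pct", delimiter="\t", comments="")
    manifest["artifacts"]["funconn"] = str(out / "funconn_edges.tsv")
    note("funconn", n_edges=len(graph.edges), fc_hubs=[int(h) for h in fc_hubs])

    # 5. perturbation protocols
    baseline = baseline_variability(net, n_runs=n_baseline_runs, window_s=window_s,
                                    seed=int(rng.integers(2**31)), burn_in_s=burn_in_s)
    note("baseline", mean=baseline.mean, sd=baseline.sd, usable=baseline.usable)
    if not baseline.usable:
        manifest["driver_report"] = None
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    pert_seed = int(rng.integers(2**31))
    snd_targets = range(net.n) if snd_neurons is None else snd_neurons
    snd = {nid: snd_experiment(net, nid, baseline, window_s, pert_seed, burn_in_s)
           for nid in snd_targets}
    targets = range(net.n) if sns_neurons is None else sns_neurons
    sweeps = {}
    for nid in targets:
        sweeps[nid] = sweep_sns(net, nid, baseline,
                                i_min=min(sns_grid), i_max=max(sns_grid),
                                step=(sns_grid[1] - sns_grid[0]) if len(sns_grid) > 1 else 1.0,
                                window_s=window_s, seed=pert_seed, burn_in_s=burn_in_s)
    report = classify_drivers(snd, sweeps, baseline)
    (out / "driver_report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    manifest["artifacts"]["driver_report"] = str(out / "driver_report.json")
    manifest["driver_report"] = report.to_json_dict()
    note("perturb", hubs=list(report.hub_set), lc1=list(report.lc1_set),
         lc2=list(report.lc2_set))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
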