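"""Deterministic micro-network fixtures.

Hand-built motifs that isolate, at the smallest possible scale, the
mechanisms the full model relies on:

* ``pair_entrain`` — a suprathreshold excitatory cell driving a
  subthreshold inhibitory one through a facilitating synapse; the
  inhibitory cell locks 1:1 to its driver.
* ``gate`` — an e -> i -> e motif where an entrained interneuron slows
  a second pacemaker; removing the interneuron speeds the target up.
* ``chain6`` — a six-neuron excitatory chain headed by a pacemaker:
  every cycle is a stereotyped ordered burst (a single route with
  fixed inter-neuron delays), the micro-analogue of a functional
  clique.
* ``lc_probe`` — ``chain6`` plus a silent inhibitory gate onto the
  chain and a silent, well-connected excitatory cell wired onto that
  gate: deleting the probe cell changes nothing, stimulating it
  silences the bursts (a low functionally connected driver).

These networks are regular ``NetworkRealization`` objects and run
through every analysis stage.
"""

from __future__ import annotations

import numpy as np

from .netgen import NetworkRealization

__all__ = ["generate_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("pair_entrain", "gate", "chain6", "lc_probe")


def _assemble(n, inhibitory_ids, excitability, edges) -> NetworkRealization:
    """Build a NetworkRealization from explicit per-edge parameters.

    ``edges``: list of (post, pre, |G|, T_I, T_R, T_F_or_None, U); the
    coupling sign follows the presynaptic class.
    """
    inh = np.zeros(n, dtype=bool)
    inh[list(inhibitory_ids)] = True
    adj = np.zeros((n, n), dtype=np.uint8)
    rows = sorted(edges)
    post = np.array([r[0] for r in rows], dtype=np.int32)
    pre = np.array([r[1] for r in rows], dtype=np.int32)
    adj[post, pre] = 1
    g = np.array([r[2] for r in rows], dtype=float)
    g[inh[pre]] *= -1.0
    net = NetworkRealization(
        adjacency=adj,
        inhibitory=inh,
        excitability=np.asarray(excitability, dtype=float),
        edge_post=post,
        edge_pre=pre,
        coupling=g,
        decay=np.array([r[3] for r in rows], dtype=float),
        recovery=np.array([r[4] for r in rows], dtype=float),
        facilitation_tau=np.array(
            [np.nan if r[5] is None else r[5] for r in rows], dtype=float),
        baseline_u=np.array([r[6] for r in rows], dtype=float),
    )
    net.validate()
    return net


def generate_fixture(name: str) -> NetworkRealization:
    """Return the named deterministic micro-network."""
    if name == "pair_entrain":
        # 0: excitatory pacemaker (natural period 52.15 ms)
        # 1: inhibitory, subthreshold, facilitating input from 0
        return _assemble(
            n=2,
            inhibitory_ids=[1],
            excitability=[15.32, 14.90],
            edges=[(1, 0, 45.0, 3.0, 100.0, 1000.0, 0.04)],
        )
    if name == "gate":
        # 0 -> 1 (entrainment) and 1 -| 2 (inhibitory gate on a pacemaker)
        return _assemble(
            n=3,
            inhibitory_ids=[1],
            excitability=[15.32, 14.90, 15.20],
            edges=[
                (1, 0, 45.0, 3.0, 100.0, 1000.0, 0.04),
                (2, 1, 135.0, 3.0, 800.0, None, 0.5),
            ],
        )
    if name == "chain6":
        # pacemaker 0 heads an excitatory chain 0->1->2->3->4->5; short
        # recovery keeps the synapses replenished so the inter-neuron
        # delays are stationary and the route unique
        edges = [(k + 1, k, 12.0, 3.0, 50.0, None, 0.5) for k in range(5)]
        return _assemble(
            n=6,
            inhibitory_ids=[],
            excitability=[15.32, 14.90, 14.90, 14.90, 14.90, 14.90],
            edges=edges,
        )
    if name == "lc_probe":
        # chain6 plus: silent inhibitory gate 6 -| chain node 1, and a
        # silent excitatory probe 7 -> 6.  Node 1 normalises its input
        # over K^I = 2, so its chain synapse is doubled to keep the
        # control dynamics identical to chain6.
        edges = [(k + 1, k, 12.0 if k > 0 else 24.0, 3.0, 50.0, None, 0.5)
                 for k in range(5)]
        edges += [
            (1, 6, 240.0, 3.0, 100.0, None, 0.5),    # inhibitory gate on the chain
            (6, 7, 45.0, 3.0, 100.0, 1000.0, 0.04),  # probe drives the gate
        ]
        return _assemble(
            n=8,
            inhibitory_ids=[6],
            excitability=[15.32, 14.90, 14.90, 14.90, 14.90, 14.90, 14.60, 14.50],
            edges=edges,
        )
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
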