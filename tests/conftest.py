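"""Shared fixtures: micro-networks, random motifs, reusable simulations."""

import numpy as np
import pytest

import burstclique as bc
from burstclique.netgen import NetworkRealization


def make_random_motif(n: int, seed: int, p: float = 0.5) -> NetworkRealization:
    """Small dense random network with realistic parameter classes."""
    r = np.random.default_rng(seed)
    adj = (r.random((n, n)) < p).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    inh = r.random(n) < 0.3
    post, pre = np.nonzero(adj)
    order = np.lexsort((pre, post))
    post, pre = post[order], pre[order]
    post_inh = inh[post]
    pre_inh = inh[pre]
    g = np.abs(r.normal(np.where(post_inh, 180.0, np.where(pre_inh, 135.0, 45.0)), 30.0)) + 1.0
    g[pre_inh] *= -1.0
    ti = np.abs(r.normal(3.0, 1.0, post.size)) + 0.5
    tr = np.where(post_inh, 100.0, 800.0) * (np.abs(r.normal(1.0, 0.2, post.size)) + 0.1)
    tf = np.where(post_inh, np.abs(r.normal(1000.0, 200.0, post.size)) + 1.0, np.nan)
    u = np.clip(r.normal(np.where(post_inh, 0.04, 0.5), 0.1), 0.01, 0.95)
    exc = r.uniform(14.8, 15.6, n)
    net = NetworkRealization(
        adjacency=adj, inhibitory=inh, excitability=exc,
        edge_post=post.astype(np.int32), edge_pre=pre.astype(np.int32),
        coupling=g, decay=ti, recovery=tr, facilitation_tau=tf, baseline_u=u,
    )
    net.validate()
    return net


def single_neuron_net(i_b: float) -> NetworkRealization:
    return NetworkRealization(
        adjacency=np.zeros((1, 1), dtype=np.uint8),
        inhibitory=np.zeros(1, dtype=bool),
        excitability=np.array([i_b]),
        edge_post=np.empty(0, np.int32), edge_pre=np.empty(0, np.int32),
        coupling=np.empty(0), decay=np.empty(0), recovery=np.empty(0),
        facilitation_tau=np.empty(0), baseline_u=np.empty(0),
    )


@pytest.fixture(scope="session")
def chain6_run():
    """chain6 fixture simulated for 5 s (no burn-in transient needed beyond 2 s)."""
    net = bc.generate_fixture("chain6")
    spikes = bc.simulate(net, 5000.0, seed=1, burn_in_ms=2000.0)
    catalog = bc.detect_pbs(spikes)
    return net, spikes, catalog


@pytest.fixture(scope="session")
def correlated_run():
    """One bursting anti-correlated N=100 realization over the 84 s window."""
    net = bc.build_network(bc.NetworkConfig(seed=3))
    spikes = bc.simulate(net, 84_000.0, seed=103, burn_in_ms=10_000.0)
    catalog = bc.detect_pbs(spikes)
    return net, spikes, catalog
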