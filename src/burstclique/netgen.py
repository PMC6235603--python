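"""Construction of network realizations.

A realization consists of a directed Erdos-Renyi adjacency matrix, a
partition of the neurons into excitatory and inhibitory classes, flat-
distributed intrinsic excitabilities anti-correlated with the total
structural degree (the developmental rule: more excitable cells are
less connected), and per-edge synaptic parameters drawn from class-
dependent Gaussians truncated to the physical domain.

Index convention: ``adjacency[i, j] == 1`` means the presynaptic neuron
``j`` projects onto the postsynaptic neuron ``i``; all per-edge tables
use (post, pre) subscripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import InvalidConfigError, NetworkConfig
from .constants import V_TH

_NET_HEADER = "#burstclique-network v1"

# clipping bounds for the release fraction U (the Gaussian draw may
# otherwise leave (0, 1), which the synaptic update rule cannot accept)
_U_LO, _U_HI = 1e-3, 1.0 - 1e-3


@dataclass
class NetworkRealization:
    """Static description of one network instance.

    All per-edge arrays are aligned with ``edge_post``/``edge_pre``
    (edges sorted by post index, then pre index).  ``coupling`` is the
    signed coupling G in mV (negative iff the presynaptic neuron is
    inhibitory); ``facilitation_tau`` is NaN on edges onto excitatory
    postsynaptic neurons, which have no facilitation dynamics.
    """

    adjacency: np.ndarray            # (n, n) uint8, [post, pre]
    inhibitory: np.ndarray           # (n,) bool
    excitability: np.ndarray         # (n,) float, I^b in mV
    edge_post: np.ndarray            # (E,) int32
    edge_pre: np.ndarray             # (E,) int32
    coupling: np.ndarray             # (E,) float, signed G in mV
    decay: np.ndarray                # (E,) float, T^I in ms
    recovery: np.ndarray             # (E,) float, T^R in ms
    facilitation_tau: np.ndarray     # (E,) float, T^F in ms or NaN
    baseline_u: np.ndarray           # (E,) float, U in (0, 1)
    config: NetworkConfig | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_post.size

    @property
    def in_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def out_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    @property
    def total_degree(self) -> np.ndarray:
        return self.in_degree + self.out_degree

    def validate(self) -> None:
        adj = self.adjacency
        if np.any(np.diag(adj)):
            raise ValueError("adjacency has self-loops")
        if adj[self.edge_post, self.edge_pre].min(initial=1) != 1:
            raise ValueError("edge list inconsistent with adjacency")
        if self.edge_post.size != int(adj.sum()):
            raise ValueError("edge count inconsistent with adjacency")
        if np.any(self.coupling == 0):
            raise ValueError("zero coupling on an existing edge")
        pre_inh = self.inhibitory[self.edge_pre]
        if np.any((self.coupling < 0) != pre_inh):
            raise ValueError("coupling sign must be negative iff presynaptic neuron is inhibitory")
        for name in ("decay", "recovery"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        post_inh = self.inhibitory[self.edge_post]
        tf = self.facilitation_tau
        if np.any(~np.isfinite(tf[post_inh])) or np.any(tf[post_inh] <= 0):
            raise ValueError("facilitation_tau must be positive on edges onto inhibitory neurons")
        if not np.all(np.isnan(tf[~post_inh])):
            raise ValueError("facilitation_tau must be NaN on edges onto excitatory neurons")
        if np.any((self.baseline_u <= 0) | (self.baseline_u >= 1)):
            raise ValueError("baseline_u must lie strictly inside (0, 1)")

    # ------------------------------------------------------------------
    # serialization: a neuron TSV and an edge TSV, round-trippable
    # ------------------------------------------------------------------
    def to_files(self, neurons_path: str | Path, edges_path: str | Path) -> None:
        n_lines = [_NET_HEADER, "id\tclass\tI_b"]
        for i in range(self.n):
            cls = "i" if self.inhibitory[i] else "e"
            n_lines.append(f"{i}\t{cls}\t{float(self.excitability[i])!r}")
        Path(neurons_path).write_text("\n".join(n_lines) + "\n")

        e_lines = [_NET_HEADER, "post_id\tpre_id\tG\tT_I\tT_R\tT_F\tU"]
        for k in range(self.n_edges):
            tf = self.facilitation_tau[k]
            tf_s = "NA" if np.isnan(tf) else repr(float(tf))
            e_lines.append(
                f"{self.edge_post[k]}\t{self.edge_pre[k]}\t"
                f"{float(self.coupling[k])!r}\t{float(self.decay[k])!r}\t"
                f"{float(self.recovery[k])!r}\t{tf_s}\t{float(self.baseline_u[k])!r}"
            )
        Path(edges_path).write_text("\n".join(e_lines) + "\n")

    @classmethod
    def from_files(cls, neurons_path: str | Path, edges_path: str | Path) -> "NetworkRealization":
        for p in (neurons_path, edges_path):
            first = Path(p).read_text().splitlines()[0]
            if first != _NET_HEADER:
                raise ValueError(f"{p}: unrecognized header {first!r}")
        ndf = pd.read_csv(neurons_path, sep="\t", skiprows=1,
                          float_precision="round_trip")
        edf = pd.read_csv(edges_path, sep="\t", skiprows=1, na_values=["NA"],
                          float_precision="round_trip")
        n = len(ndf)
        adj = np.zeros((n, n), dtype=np.uint8)
        post = edf["post_id"].to_numpy(np.int32)
        pre = edf["pre_id"].to_numpy(np.int32)
        adj[post, pre] = 1
        net = cls(
            adjacency=adj,
            inhibitory=(ndf["class"].to_numpy() == "i"),
            excitability=ndf["I_b"].to_numpy(float),
            edge_post=post,
            edge_pre=pre,
            coupling=edf["G"].to_numpy(float),
            decay=edf["T_I"].to_numpy(float),
            recovery=edf["T_R"].to_numpy(float),
            facilitation_tau=edf["T_F"].to_numpy(float),
            baseline_u=edf["U"].to_numpy(float),
        )
        net.validate()
        return net


def build_er_digraph(n: int, mean_in_degree: float, seed=None) -> np.ndarray:
    """Directed Erdos-Renyi adjacency matrix without self-loops.

    Each off-diagonal entry is independently present with probability
    ``mean_in_degree / (n - 1)``, so both the mean in-degree and the
    mean out-degree equal ``mean_in_degree``.
    """
    if not 0 < mean_in_degree < n:
        raise InvalidConfigError(
            f"mean_in_degree must lie in (0, n); got {mean_in_degree} for n={n}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = min(mean_in_degree / (n - 1), 1.0)
    adj = (rng.random((n, n)) < p).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


def sample_excitabilities(
    n: int,
    center: float = V_TH,
    width: float = 0.45,
    frac_supra: float = 0.10,
    seed=None,
    threshold: float = V_TH,
) -> np.ndarray:
    """Flat-distributed intrinsic excitabilities with an exact suprathreshold count.

    Values are uniform on ``[center - width, center + width]`` (``width``
    is the half-width: the default 0.45 mV around 15 mV spans
    [14.55, 15.45] mV, whose suprathreshold edge reproduces the ~22 Hz
    maximal control firing rate), conditioned on exactly
    ``round(frac_supra * n)`` of them lying strictly above
    ``threshold``: the suprathreshold values are drawn uniformly from
    ``(threshold, center + width]`` and the rest from
    ``[center - width, threshold]``, then shuffled.
    """
    if width <= 0:
        raise InvalidConfigError("width must be positive")
    if not 0 <= frac_supra <= 1:
        raise InvalidConfigError("frac_supra must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = center - width, center + width
    k = int(round(frac_supra * n))
    if k > 0 and hi <= threshold:
        raise InvalidConfigError("support has no mass above threshold but frac_supra > 0")
    if k < n and lo > threshold:
        raise InvalidConfigError("support has no mass below threshold but frac_supra < 1")
    supra = threshold + (hi - threshold) * (1.0 - rng.random(k))   # in (threshold, hi]
    sub = lo + (min(threshold, hi) - lo) * rng.random(n - k)       # in [lo, threshold)
    values = np.concatenate([supra, sub])
    rng.shuffle(values)
    return values


def assign_anticorrelated(excitabilities: np.ndarray, total_degrees: np.ndarray) -> np.ndarray:
    """Permute excitabilities so the best connected neuron is the least excitable.

    The neuron with the r-th largest total degree receives the r-th
    smallest excitability; the Spearman correlation between the two is
    -1 up to ties.  Ties in degree are broken by neuron index (stable
    sort), making the assignment deterministic.
    """
    exc = np.asarray(excitabilities, dtype=float)
    deg = np.asarray(total_degrees)
    if exc.shape != deg.shape:
        raise ValueError("excitabilities and total_degrees must have equal length")
    order_deg = np.argsort(-deg, kind="stable")   # descending degree, index tie-break
    sorted_exc = np.sort(exc)                     # ascending excitability
    out = np.empty_like(exc)
    out[order_deg] = sorted_exc
    return out


def sample_synaptic_params(
    adjacency: np.ndarray,
    inhibitory: np.ndarray,
    config: NetworkConfig | None = None,
    seed=None,
) -> dict[str, np.ndarray]:
    """Draw per-edge synaptic parameters from class-dependent Gaussians.

    Means depend on the (post, pre) classes of each edge; the SD is
    ``config.sd_factor`` times the mean.  Time constants and coupling
    magnitudes are redrawn until strictly positive; U is clipped to
    (0, 1).  The coupling sign is negative iff the presynaptic neuron
    is inhibitory.  Returns a dict of edge arrays sorted by
    (post, pre), keyed as the corresponding NetworkRealization fields.
    """
    cfg = config if config is not None else NetworkConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    post, pre = np.nonzero(adjacency)
    order = np.lexsort((pre, post))
    post, pre = post[order].astype(np.int32), pre[order].astype(np.int32)
    post_inh = inhibitory[post]
    pre_inh = inhibitory[pre]
    n_edges = post.size

    def draw_positive(mean: np.ndarray) -> np.ndarray:
        out = rng.normal(mean, cfg.sd_factor * mean)
        bad = out <= 0
        while np.any(bad):
            out[bad] = rng.normal(mean[bad], cfg.sd_factor * mean[bad])
            bad = out <= 0
        return out

    t_decay = draw_positive(np.full(n_edges, cfg.t_decay_mean))
    t_rec = draw_positive(
        np.where(post_inh, cfg.t_recovery_mean_ipost, cfg.t_recovery_mean_epost)
    )
    t_fac = np.full(n_edges, np.nan)
    if np.any(post_inh):
        t_fac[post_inh] = draw_positive(
            np.full(int(post_inh.sum()), cfg.t_facil_mean)
        )
    u_mean = np.where(post_inh, cfg.u_mean_ipost, cfg.u_mean_epost)
    u = np.clip(rng.normal(u_mean, cfg.sd_factor * u_mean), _U_LO, _U_HI)
    g_mean = np.where(
        post_inh,
        np.where(pre_inh, cfg.g_mean_ii, cfg.g_mean_ie),
        np.where(pre_inh, cfg.g_mean_ei, cfg.g_mean_ee),
    )
    g = draw_positive(g_mean)
    g[pre_inh] *= -1.0
    return {
        "edge_post": post,
        "edge_pre": pre,
        "coupling": g,
        "decay": t_decay,
        "recovery": t_rec,
        "facilitation_tau": t_fac,
        "baseline_u": u,
    }


def build_network(config: NetworkConfig | None = None, seed=None) -> NetworkRealization:
    """Build a complete network realization from a configuration.

    With ``config.correlated`` (the default) the excitabilities are
    assigned anti-correlated with the total structural degree; the
    uncorrelated control variant assigns them in the random order they
    were drawn.
    """
    cfg = config if config is not None else NetworkConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    adj = build_er_digraph(cfg.n_total, cfg.mean_in_degree, rng)
    inhibitory = np.zeros(cfg.n_total, dtype=bool)
    inhibitory[rng.choice(cfg.n_total, size=cfg.n_inh, replace=False)] = True
    exc = sample_excitabilities(
        cfg.n_total, cfg.excitability_center, cfg.excitability_width,
        cfg.frac_suprathreshold, rng,
    )
    if cfg.correlated:
        total_deg = adj.sum(axis=1) + adj.sum(axis=0)
        exc = assign_anticorrelated(exc, total_deg)
    params = sample_synaptic_params(adj, inhibitory, cfg, rng)
    net = NetworkRealization(
        adjacency=adj,
        inhibitory=inhibitory,
        excitability=exc,
        config=cfg,
        **params,
    )
    net.validate()
    return net
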