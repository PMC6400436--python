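"""Global weighted-network metrics.

Five whole-graph summaries of segregation and integration are computed from
a :class:`~netnorm.network.WeightedNetwork`:

``clustering_coefficient``
    Mean over nodes of the geometric-mean (Onnela) triangle intensity,
    ``C_i = sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3} / (k_i (k_i - 1))`` with
    weights normalized by the network maximum (``w' = w / max w``).  Nodes
    with binary degree < 2 contribute 0.
``transitivity``
    Network-level ratio of total triangle intensity to total connected
    triples, ``sum_i t_i / sum_i k_i (k_i - 1)`` — a single ratio, not a
    node average.
``modularity``
    Newman weighted modularity ``Q`` of the best partition found by Louvain
    community detection with seeded restarts.
``characteristic_path_length``
    Mean shortest-path distance over ordered node pairs with edge length
    ``1 / w``; unreachable pairs are excluded and their fraction reported.
``global_efficiency``
    Mean of ``1 / d_ij`` over ordered pairs, with ``1/inf = 0`` so
    disconnection is handled intrinsically.

Clustering and transitivity are invariant to a global rescaling of weights
(max-normalization); path length scales like ``1/c`` and efficiency like
``c`` under ``w -> c w``.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from ._seeds import derive
from .network import WeightedNetwork

#: Canonical order of the five global metrics throughout the package.
METRIC_NAMES = (
    "clustering_coefficient",
    "transitivity",
    "modularity",
    "characteristic_path_length",
    "global_efficiency",
)


@dataclass
class GlobalMetrics:
    """The five global metrics for one network, plus bookkeeping counts."""

    clustering_coefficient: float
    transitivity: float
    modularity: float
    characteristic_path_length: float
    global_efficiency: float
    n_nodes: int
    n_edges: int
    disconnected_pair_fraction: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in METRIC_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in METRIC_NAMES}


def _triangle_intensities(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node triangle intensity t_i and binary degree k_i.

    t_i = sum_{j,h} (w'_ij w'_jh w'_hi)^(1/3) = (S^3)_ii for S = cbrt(W').
    """
    a = net.adjacency
    wmax = a.max()
    if wmax == 0:
        return np.zeros(net.n_nodes), np.zeros(net.n_nodes, dtype=int)
    s = sparse.csr_matrix(np.cbrt(a / wmax))
    t = np.asarray((s @ s).multiply(s).sum(axis=1)).ravel()
    k = net.degrees()
    return t, k


def weighted_clustering(net: WeightedNetwork) -> float:
    """Mean Onnela weighted clustering coefficient (max-normalized weights)."""
    if net.n_nodes == 0 or net.n_edges == 0:
        return 0.0
    t, k = _triangle_intensities(net)
    c = np.zeros(net.n_nodes)
    mask = k >= 2
    c[mask] = t[mask] / (k[mask] * (k[mask] - 1))
    return float(c.mean())


def transitivity(net: WeightedNetwork) -> float:
    """Weighted transitivity: total triangle intensity over total triples."""
    if net.n_nodes == 0 or net.n_edges == 0:
        return 0.0
    t, k = _triangle_intensities(net)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        warnings.warn("network has no connected triples; transitivity set to 0")
        return 0.0
    return float(t.sum() / denom)


def newman_modularity(net: WeightedNetwork, membership: np.ndarray) -> float:
    """Weighted Newman modularity Q of a given node partition.

    Q = (1/2m) sum_ij [w_ij - s_i s_j / 2m] delta(c_i, c_j), with s the node
    strengths and 2m the total weight.
    """
    a = net.adjacency
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("modularity is undefined for an empty graph")
    s = net.strengths()
    membership = np.asarray(membership)
    q = 0.0
    for c in np.unique(membership):
        idx = membership == c
        q += a[np.ix_(idx, idx)].sum() / two_m - (s[idx].sum() / two_m) ** 2
    return float(q)


def _local_move_refinement(
    net: WeightedNetwork, membership: np.ndarray, max_passes: int = 20
) -> np.ndarray:
    """Greedy single-node moves (to a neighboring or fresh community) until
    no move increases Q — the flat-level completion of Louvain's first phase.
    """
    a = net.adjacency
    n = net.n_nodes
    two_m = a.sum()
    m = two_m / 2.0
    s = net.strengths()
    membership = membership.copy()
    neighbors = [np.nonzero(a[i])[0] for i in range(n)]
    comm_strength = np.zeros(n + n)  # room for fresh community labels
    for i in range(n):
        comm_strength[membership[i]] += s[i]
    next_label = int(membership.max()) + 1
    for _ in range(max_passes):
        improved = False
        for i in range(n):
            c = membership[i]
            w_to = {}
            for j in neighbors[i]:
                w_to[membership[j]] = w_to.get(membership[j], 0.0) + a[i, j]
            w_ic = w_to.get(c, 0.0)
            best_gain, best_d = 0.0, c
            candidates = list(w_to.keys()) + [next_label]
            for d in candidates:
                if d == c:
                    continue
                w_id = w_to.get(d, 0.0)
                gain = (w_id - w_ic) / m - s[i] * (
                    comm_strength[d] - comm_strength[c] + s[i]
                ) / (2.0 * m * m)
                if gain > best_gain + 1e-15:
                    best_gain, best_d = gain, d
            if best_d != c:
                comm_strength[c] -= s[i]
                comm_strength[best_d] += s[i]
                membership[i] = best_d
                if best_d == next_label:
                    next_label += 1
                    if next_label >= len(comm_strength):
                        comm_strength = np.concatenate([comm_strength, np.zeros(n)])
                improved = True
        if not improved:
            break
    return membership


def _merge_refinement(net: WeightedNetwork, membership: np.ndarray) -> np.ndarray:
    """Greedy community merges while any merge increases Q."""
    a = net.adjacency
    two_m = a.sum()
    labels, membership = np.unique(membership, return_inverse=True)
    c = len(labels)
    if c < 2:
        return membership
    ind = np.zeros((net.n_nodes, c))
    ind[np.arange(net.n_nodes), membership] = 1.0
    w_cc = ind.T @ a @ ind  # community-by-community weight totals
    s_c = ind.T @ net.strengths()
    alive = np.ones(c, dtype=bool)
    while True:
        gains = 2.0 * w_cc / two_m - 2.0 * np.outer(s_c, s_c) / two_m**2
        gains[~alive, :] = -np.inf
        gains[:, ~alive] = -np.inf
        np.fill_diagonal(gains, -np.inf)
        x, y = np.unravel_index(int(np.argmax(gains)), gains.shape)
        if gains[x, y] <= 1e-15:
            return membership
        membership[membership == y] = x
        w_cc[x, :] += w_cc[y, :]
        w_cc[:, x] += w_cc[:, y]
        s_c[x] += s_c[y]
        alive[y] = False


def modularity(
    net: WeightedNetwork, seed: int, n_restarts: int = 10
) -> tuple[float, np.ndarray]:
    """Maximize weighted modularity with Louvain, best of ``n_restarts``.

    Each restart is followed by a greedy single-node refinement pass at the
    flat level, which repairs the coarse local optima Louvain's aggregation
    can leave behind on small graphs.  Returns ``(Q, membership)`` of the
    best partition.  Deterministic given ``seed``; the single-community
    partition is always a candidate, so the returned Q is never negative
    for graphs with no community structure.
    """
    import igraph as ig

    if net.n_edges == 0:
        raise ValueError("modularity is undefined for an empty graph")
    n = net.n_nodes
    iu, iv, w = net.edge_array()
    best_q = newman_modularity(net, np.zeros(n, dtype=int))
    best_membership = np.zeros(n, dtype=int)
    state = _pyrandom.getstate()
    try:
        for r in range(n_restarts):
            rng = np.random.default_rng(derive(seed, 71, r))
            # permute node order: igraph's sweep order is index-driven, so
            # relabeling is what actually diversifies restarts
            perm = rng.permutation(n) if r > 0 else np.arange(n)
            inv = np.empty(n, dtype=int)
            inv[perm] = np.arange(n)
            g = ig.Graph(
                n=n, edges=list(zip(inv[iu].tolist(), inv[iv].tolist()))
            )
            _pyrandom.seed(derive(seed, 72, r))
            clustering = g.community_multilevel(weights=w.tolist())
            memb_perm = np.asarray(clustering.membership, dtype=int)
            membership = memb_perm[inv]
            if n <= 256:
                # refinement pays off only on small graphs, where Louvain's
                # aggregation leaves coarse local optima; at scale the
                # multilevel pass already merges exhaustively
                for _ in range(2):
                    membership = _local_move_refinement(net, membership)
                    membership = _merge_refinement(net, membership)
            q = newman_modularity(net, membership)
            if q > best_q:
                best_q, best_membership = q, membership
        if n <= 24:
            # tiny graphs have rugged Q landscapes that defeat Louvain's
            # aggregation; cheap basin hopping from random partitions
            rng = np.random.default_rng(derive(seed, 73))
            for _ in range(30):
                membership = rng.integers(0, max(2, n // 2), size=n)
                for _ in range(3):
                    membership = _local_move_refinement(net, membership)
                    membership = _merge_refinement(net, membership)
                q = newman_modularity(net, membership)
                if q > best_q:
                    best_q, best_membership = q, membership
    finally:
        _pyrandom.setstate(state)
    return best_q, best_membership


def _shortest_path_matrix(net: WeightedNetwork) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    a = net.adjacency
    iu, iv, w = net.edge_array()
    n = net.n_nodes
    lengths = sparse.csr_matrix((1.0 / w, (iu, iv)), shape=(n, n))
    return dijkstra(lengths, directed=False)


def characteristic_path_length(
    net: WeightedNetwork, return_disconnected_fraction: bool = False
):
    """Mean shortest-path length over reachable ordered pairs.

    Edge length is the inverse weight.  Pairs with no connecting path are
    excluded from the mean; optionally the excluded fraction is returned.
    """
    if net.n_nodes < 2:
        raise ValueError("path length requires at least 2 nodes")
    d = _shortest_path_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("no finite node pairs; graph has no edges")
    frac_excluded = 1.0 - n_finite / int(off.sum())
    length = float(d[finite].mean())
    if return_disconnected_fraction:
        return length, frac_excluded
    return length


def global_efficiency(net: WeightedNetwork) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    if net.n_nodes < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    if net.n_edges == 0:
        return 0.0
    d = _shortest_path_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def compute_all(net: WeightedNetwork, seed: int, louvain_restarts: int = 10) -> GlobalMetrics:
    """Compute all five global metrics for one network.

    A single Dijkstra pass is shared between path length and efficiency.
    """
    if net.n_edges == 0:
        raise ValueError("cannot compute global metrics on an empty graph")
    t, k = _triangle_intensities(net)
    c_nodes = np.zeros(net.n_nodes)
    mask = k >= 2
    c_nodes[mask] = t[mask] / (k[mask] * (k[mask] - 1))
    clustering = float(c_nodes.mean())
    triples = float((k * (k - 1)).sum())
    trans = float(t.sum() / triples) if triples > 0 else 0.0

    q, _ = modularity(net, seed=seed, n_restarts=louvain_restarts)

    d = _shortest_path_matrix(net)
    n = net.n_nodes
    isfin = np.isfinite(d)
    np.fill_diagonal(isfin, False)
    vals = d[isfin]  # finite off-diagonal distances, all > 0
    n_off = n * n - n
    n_finite = vals.size
    if n_finite == 0:
        raise ValueError("no finite node pairs; graph has no edges")
    length = float(vals.mean())
    frac_excluded = 1.0 - n_finite / n_off
    efficiency = float((1.0 / vals).sum() / n_off)

    return GlobalMetrics(
        clustering_coefficient=clustering,
        transitivity=trans,
        modularity=q,
        characteristic_path_length=length,
        global_efficiency=efficiency,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        disconnected_pair_fraction=frac_excluded,
    )
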