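"""Graph statistics for binary and weighted undirected brain networks.

Conventions follow the standard network-neuroscience definitions: weighted
shortest paths use the reciprocal weight-to-length transform L_ij = 1/W_ij;
betweenness is normalized by (N-1)(N-2) over ordered node pairs; modularity
uses the degree-preserving (Newman-Girvan) null with resolution parameter
gamma, optimized by repeated seeded Louvain runs keeping the best-Q
partition.  Clustering defaults to the binary triangle formula, with the
Onnela geometric-mean weighted variant behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

__all__ = [
    "CommunityPartition",
    "assortativity",
    "betweenness",
    "clustering",
    "degrees",
    "diameter",
    "edge_lengths",
    "efficiency",
    "global_measures",
    "mean_clustering",
    "modularity_louvain",
    "modularity_sweep",
    "modularity_value",
    "participation",
    "path_length",
    "shortest_paths",
    "strengths",
    "total_weight",
]

DEFAULT_GAMMA_GRID = np.round(np.arange(0.7, 2.1 + 1e-9, 0.1), 10)


def _as_matrix(net) -> np.ndarray:
    """Accept a GroupNetwork-like object or a plain (N, N) array."""
    w = getattr(net, "weights", net)
    return np.asarray(w, dtype=float)


# ---------------------------------------------------------------------------
# degree, strength, clustering


def degrees(net) -> np.ndarray:
    """Binary degree k_i: number of connections of each node."""
    a = _as_matrix(net) > 0
    return a.sum(axis=1).astype(float)


def strengths(net) -> np.ndarray:
    """Weighted degree (strength): summed connection weight per node."""
    return _as_matrix(net).sum(axis=1)


def total_weight(net, weighted: bool = True) -> float:
    """2m: total (doubled) connection weight, or count if binary."""
    return float(strengths(net).sum()) if weighted else float(degrees(net).sum())


def clustering(net, weighted: bool = False) -> np.ndarray:
    """Nodal clustering coefficient c_i = 2 t_i / (k_i (k_i - 1)).

    The binary form counts triangles on the binarized graph.  With
    ``weighted=True`` triangles are scored by the geometric mean of their
    weights scaled to the network maximum (Onnela variant).
    """
    w = _as_matrix(net)
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if weighted:
        wmax = w.max()
        if wmax == 0:
            return np.zeros(len(w))
        cw = np.cbrt(w / wmax)
        t = np.diag(cw @ cw @ cw) / 2.0
    else:
        t = np.diag(a @ a @ a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1), 0.0)
    return c


def mean_clustering(net, weighted: bool = False) -> float:
    return float(clustering(net, weighted=weighted).mean())


# ---------------------------------------------------------------------------
# shortest paths and derived measures


@dataclass(frozen=True)
class ShortestPathMatrix:
    entries: np.ndarray
    weighted: bool

    @property
    def connected(self) -> bool:
        return bool(np.isfinite(self.entries).all())


def shortest_paths(net, weighted: bool = False) -> ShortestPathMatrix:
    """All-pairs shortest path lengths; weighted paths use lengths 1/W_ij."""
    w = _as_matrix(net)
    if weighted:
        if np.any((w != 0) & ~(w > 0)):
            raise ValueError("weighted shortest paths need positive weights")
        with np.errstate(divide="ignore"):
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
        d = _csgraph_shortest_path(lengths, method="D", directed=False)
    else:
        d = _csgraph_shortest_path((w > 0).astype(float), directed=False, unweighted=True)
    np.fill_diagonal(d, 0.0)
    return ShortestPathMatrix(d, weighted)


def _upper_vals(d: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(d.shape[0], k=1)
    return d[iu, ju]


def path_length(sp: ShortestPathMatrix) -> float:
    """Characteristic path length; infinite when the graph is disconnected."""
    return float(_upper_vals(sp.entries).mean())


def path_length_finite(sp: ShortestPathMatrix) -> float:
    """Mean shortest path over connected (finite) pairs only."""
    v = _upper_vals(sp.entries)
    v = v[np.isfinite(v)]
    return float(v.mean()) if v.size else float("nan")


def diameter(sp: ShortestPathMatrix) -> float:
    """Longest finite shortest path."""
    v = _upper_vals(sp.entries)
    v = v[np.isfinite(v)]
    return float(v.max()) if v.size else float("nan")


def efficiency(sp: ShortestPathMatrix) -> float:
    """Mean inverse shortest path length; disconnected pairs contribute 0."""
    v = _upper_vals(sp.entries)
    with np.errstate(divide="ignore"):
        inv = np.where(v > 0, 1.0 / np.where(v > 0, v, 1.0), 0.0)
    inv[~np.isfinite(v)] = 0.0
    return float(inv.mean())


def _to_graph(w: np.ndarray, weighted: bool) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(w)))
    iu, ju = np.nonzero(np.triu(w, 1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        g.add_edge(i, j, weight=float(w[i, j]), length=1.0 / float(w[i, j]))
    return g


def betweenness(net, weighted: bool = False) -> np.ndarray:
    """Betweenness centrality, normalized over ordered pairs by (N-1)(N-2)."""
    w = _as_matrix(net)
    g = _to_graph(w, weighted)
    bc = nx.betweenness_centrality(
        g, normalized=True, weight="length" if weighted else None
    )
    return np.array([bc[i] for i in range(len(w))])


# ---------------------------------------------------------------------------
# modularity and participation


@dataclass(frozen=True)
class CommunityPartition:
    """Node-to-community assignment with its modularity value."""

    assignment: np.ndarray  # labels 1..K
    gamma: float
    q: float

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max())


def _relabel(assignment: np.ndarray) -> np.ndarray:
    """Contiguous labels 1..K in order of first appearance."""
    out = np.zeros_like(assignment)
    mapping: dict = {}
    for idx, lab in enumerate(assignment):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[idx] = mapping[lab]
    return out


def modularity_value(net, assignment: np.ndarray, gamma: float = 1.0) -> float:
    """Q(gamma) = 1/(2m) sum_{ij in same community} [A_ij - gamma k_i k_j / 2m].

    The null-model sum includes the i = j terms, the convention under which
    two disconnected equal cliques score Q = 0.5 at gamma = 1.
    """
    w = _as_matrix(net)
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for an empty graph")
    same = np.asarray(assignment)[:, None] == np.asarray(assignment)[None, :]
    b = w - gamma * np.outer(k, k) / two_m
    return float(b[same].sum() / two_m)


def _refine_partition(
    w: np.ndarray, assignment: np.ndarray, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Greedy single-node moves (seeded order) until no move improves Q.

    Louvain cannot split communities formed in its first phase; this
    polishing pass guarantees the returned partition is locally optimal
    under single-node relocation (including splitting off a singleton).
    """
    n = len(w)
    k = w.sum(axis=1)
    two_m = k.sum()
    _, assignment = np.unique(assignment, return_inverse=True)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            n_comm = int(assignment.max()) + 1
            # slot n_comm is a fresh singleton community
            w_to = np.bincount(assignment, weights=w[i], minlength=n_comm + 1)
            s = np.bincount(assignment, weights=k, minlength=n_comm + 1)
            cur = assignment[i]
            s_cur = s[cur] - k[i]  # current community without i
            s_other = s.copy()
            s_other[cur] = s_cur
            gain = 2 * (w_to - w_to[cur]) - gamma * 2 * k[i] * (s_other - s_cur) / two_m
            gain[cur] = 0.0
            best = int(np.argmax(gain))
            if gain[best] > 1e-12:
                assignment[i] = best
                improved = True
        if improved:
            _, assignment = np.unique(assignment, return_inverse=True)
            continue
        # node moves exhausted: try merging whole communities, then resume
        n_comm = int(assignment.max()) + 1
        if n_comm > 1:
            indicator = np.eye(n_comm)[assignment]
            between = indicator.T @ w @ indicator
            s = k @ indicator
            merge_gain = 2 * between - gamma * 2 * np.outer(s, s) / two_m
            np.fill_diagonal(merge_gain, -np.inf)
            a, b = np.unravel_index(np.argmax(merge_gain), merge_gain.shape)
            if merge_gain[a, b] > 1e-12:
                assignment[assignment == b] = a
                _, assignment = np.unique(assignment, return_inverse=True)
                improved = True
    return assignment


def modularity_louvain(
    net, gamma: float = 1.0, seed: int | None = None, repetitions: int = 100
) -> CommunityPartition:
    """Best-of-``repetitions`` seeded Louvain maximization of Q(gamma),
    each run polished by a greedy single-node-move refinement."""
    w = _as_matrix(net)
    if w.sum() == 0:
        raise ValueError("modularity undefined for an empty graph")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    g = _to_graph(w, weighted=True)
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best = None
    for _ in range(repetitions):
        communities = nx.community.louvain_communities(
            g,
            weight="weight",
            resolution=gamma,
            seed=int(rng.integers(2**31 - 1)),
        )
        assignment = np.zeros(len(w), dtype=int)
        for lab, nodes in enumerate(communities, start=1):
            for node in nodes:
                assignment[node] = lab
        assignment = _refine_partition(w, assignment, gamma, rng)
        q = modularity_value(w, assignment, gamma)
        if q > best_q:
            best_q, best = q, assignment
        # a refined random restart escapes basins Louvain's greedy phase
        # cannot leave (it never splits a community it has formed)
        n = len(w)
        random_start = rng.integers(0, max(2, int(rng.integers(2, n + 1))), n)
        assignment = _refine_partition(w, random_start, gamma, rng)
        q = modularity_value(w, assignment, gamma)
        if q > best_q:
            best_q, best = q, assignment
    return CommunityPartition(_relabel(best), float(gamma), best_q)


def modularity_sweep(
    net,
    gammas: np.ndarray = DEFAULT_GAMMA_GRID,
    repetitions: int = 100,
    seed: int | None = None,
) -> list[CommunityPartition]:
    """Louvain sweep over a resolution grid (default 0.7 to 2.1 by 0.1)."""
    rng = np.random.default_rng(seed)
    return [
        modularity_louvain(
            net, gamma=float(g), seed=int(rng.integers(2**31 - 1)), repetitions=repetitions
        )
        for g in gammas
    ]


def participation(net, partition) -> np.ndarray:
    """Participation coefficient p_i = 1 - sum_sigma (kappa_i,sigma / k_i)^2."""
    w = _as_matrix(net)
    assignment = np.asarray(
        getattr(partition, "assignment", partition), dtype=int
    )
    labels = np.unique(assignment)
    indicator = (assignment[:, None] == labels[None, :]).astype(float)
    kappa = w @ indicator  # (N, K) weight into each module
    k = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, kappa / np.where(k[:, None] > 0, k[:, None], 1), 0.0)
    p = 1.0 - (frac**2).sum(axis=1)
    p[k == 0] = 0.0
    return p


# ---------------------------------------------------------------------------
# assortativity and edge lengths


def assortativity(net) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees over
    edges.  Undefined (NaN, with a warning) on regular graphs."""
    w = _as_matrix(net)
    a = w > 0
    k = a.sum(axis=1).astype(float)
    iu, ju = np.nonzero(np.triu(a, 1))
    if iu.size == 0:
        raise ValueError("assortativity needs at least one edge")
    ki, kj = k[iu], k[ju]
    m = float(iu.size)
    num = (ki * kj).sum() / m - (((ki + kj) / 2).sum() / m) ** 2
    den = ((ki**2 + kj**2) / 2).sum() / m - (((ki + kj) / 2).sum() / m) ** 2
    if den == 0:
        warnings.warn("assortativity undefined: all endpoint degrees equal")
        return float("nan")
    return float(num / den)


def edge_lengths(net, dist: np.ndarray) -> np.ndarray:
    """Euclidean lengths of all retained edges (one entry per edge)."""
    w = _as_matrix(net)
    iu, ju = np.nonzero(np.triu(w, 1))
    return np.asarray(dist)[iu, ju]


# ---------------------------------------------------------------------------
# global summary


def global_measures(
    net,
    gamma: float = 1.0,
    repetitions: int = 20,
    seed: int | None = None,
) -> dict[str, float]:
    """The global statistics battery, binary and weighted analogs.

    Modularity uses best-of-``repetitions`` Louvain at resolution ``gamma``.
    """
    w = _as_matrix(net)
    out: dict[str, float] = {}
    out["n_edges"] = total_weight(w, weighted=False) / 2
    out["total_weight"] = total_weight(w, weighted=True) / 2
    out["mean_clustering_binary"] = mean_clustering(w, weighted=False)
    out["mean_clustering_weighted"] = mean_clustering(w, weighted=True)
    rng = np.random.default_rng(seed)
    for tag, weighted in (("binary", False), ("weighted", True)):
        sp = shortest_paths(w, weighted=weighted)
        out[f"efficiency_{tag}"] = efficiency(sp)
        out[f"path_length_{tag}"] = path_length_finite(sp)
        out[f"diameter_{tag}"] = diameter(sp)
        mat = (w > 0).astype(float) if not weighted else w
        if mat.sum() > 0:
            part = modularity_louvain(
                mat, gamma=gamma, seed=int(rng.integers(2**31 - 1)), repetitions=repetitions
            )
            out[f"modularity_{tag}"] = part.q
        else:
            out[f"modularity_{tag}"] = float("nan")
    try:
        out["assortativity"] = assortativity(w)
    except ValueError:
        out["assortativity"] = float("nan")
    return out
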