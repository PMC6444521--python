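"""Independent brute-force oracles for graph statistics.

Pure-Python enumeration: simple-path enumeration for shortest paths and
betweenness, exhaustive set-partition search for modularity.  Nothing here
shares code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def _edge_length(w, i, j, weighted):
    return 1.0 / w[i][j] if weighted else 1.0


def _simple_paths(adj, s, t):
    """All simple paths from s to t as node lists (DFS)."""
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + [nb]))


def _adj_list(w):
    n = len(w)
    return {i: [j for j in range(n) if j != i and w[i][j] > 0] for i in range(n)}


def brute_shortest_paths(w, weighted=False):
    """All-pairs shortest path lengths by simple-path enumeration."""
    w = np.asarray(w, dtype=float)
    n = len(w)
    adj = _adj_list(w)
    d = np.full((n, n), math.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            best = math.inf
            for path in _simple_paths(adj, s, t):
                length = sum(
                    _edge_length(w, a, b, weighted) for a, b in zip(path, path[1:])
                )
                best = min(best, length)
            d[s, t] = d[t, s] = best
    return d


def brute_betweenness(w, weighted=False, tol=1e-12):
    """Betweenness via exhaustive shortest-path enumeration, normalized over
    ordered pairs by (N-1)(N-2)."""
    w = np.asarray(w, dtype=float)
    n = len(w)
    adj = _adj_list(w)
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = []
            best = math.inf
            for path in _simple_paths(adj, s, t):
                length = sum(
                    _edge_length(w, a, b_, weighted) for a, b_ in zip(path, path[1:])
                )
                if length < best - tol:
                    best = length
                    paths = [path]
                elif abs(length - best) <= tol:
                    paths.append(path)
            if not paths:
                continue
            rho = len(paths)
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in paths if i in p[1:-1])
                b[i] += 2.0 * through / rho  # both orderings of (s, t)
    if n > 2:
        b /= (n - 1) * (n - 2)
    return b


def set_partitions(items):
    """All partitions of a list into nonempty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def modularity_of_partition(w, blocks, gamma=1.0):
    """Q = 1/(2m) sum_blocks sum_{i,j in block} [A_ij - gamma k_i k_j / 2m],
    ordered pairs including i = j in the null term."""
    w = np.asarray(w, dtype=float)
    k = w.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for block in blocks:
        idx = np.array(block)
        q += w[np.ix_(idx, idx)].sum() - gamma * np.outer(k[idx], k[idx]).sum() / two_m
    return q / two_m


def brute_max_modularity(w, gamma=1.0):
    """Exhaustive maximum of Q(gamma) over all node partitions."""
    n = len(w)
    best = -math.inf
    best_blocks = None
    for blocks in set_partitions(list(range(n))):
        q = modularity_of_partition(w, blocks, gamma)
        if q > best:
            best, best_blocks = q, blocks
    return best, best_blocks


def random_connected_graph(rng, n_min=4, n_max=8, weighted=True, p=0.5):
    """Random connected weighted graph as a symmetric matrix."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        a = rng.random((n, n)) < p
        a = np.triu(a, 1)
        w = np.where(a, rng.uniform(0.5, 2.0, (n, n)), 0.0) if weighted else a.astype(float)
        w = w + w.T
        # connectivity check by BFS
        seen = {0}
        frontier = [0]
        while frontier:
            node = frontier.pop()
            for nb in range(n):
                if w[node, nb] > 0 and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
        if len(seen) == n:
            return w
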