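"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: topology enumeration
by sequential edge insertion, ordinary least-squares branch fitting on the
path-incidence system, and exhaustive best-topology selection.
"""

from itertools import combinations

import numpy as np


def enumerate_topologies(labels):
    """All unrooted binary topologies over *labels* (3 -> 1, 4 -> 3,
    5 -> 15, 6 -> 105).  Each topology is a list of edges; internal nodes
    are integers."""
    labels = list(labels)
    base = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]
    trees = [(base, 1)]
    for leaf in labels[3:]:
        nxt = []
        for edges, n_int in trees:
            for i, (u, v) in enumerate(edges):
                new = edges[:i] + edges[i + 1 :]
                w = n_int
                new += [(u, w), (w, v), (leaf, w)]
                nxt.append((new, n_int + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _path_edges(edges, a, b):
    adj = _adjacency(edges)
    # DFS from a to b, tracking edges
    stack = [(a, None, [])]
    seen = {a}
    index = {frozenset(e): i for i, e in enumerate(edges)}
    while stack:
        node, _, path = stack.pop()
        if node == b:
            return path
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append((nb, node, path + [index[frozenset((node, nb))]]))
    raise RuntimeError("disconnected tree")


def ls_fit(edges, labels, dist):
    """Least-squares branch lengths for a fixed topology; returns SSE."""
    pairs = list(combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        for e in _path_edges(edges, labels[i], labels[j]):
            A[row, e] = 1.0
        y[row] = dist[i, j]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ x - y
    return float(resid @ resid)


def best_ls_topology(labels, dist):
    """Bipartition set of the least-squares-optimal topology."""
    best = None
    for edges in enumerate_topologies(labels):
        sse = ls_fit(edges, labels, dist)
        if best is None or sse < best[0]:
            best = (sse, edges)
    return bipartition_set(best[1], labels)


def bipartition_set(edges, labels):
    """Non-trivial bipartitions of an edge-list topology, canonicalised the
    same way as niltkit.phylo.bipartitions."""
    labelset = frozenset(labels)
    adj = _adjacency(edges)
    bips = set()
    for u, v in edges:
        # leaves on v's side when edge (u,v) removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node in labelset:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 1 < len(side) < len(labelset) - 1:
            other = labelset - side
            bips.add(min(tuple(sorted(side)), tuple(sorted(other))))
    return bips


def random_additive_matrix(labels, rng):
    """A random binary topology with positive branch lengths and its exact
    path-length distance matrix.  Returns (dist, bipartitions)."""
    tops = enumerate_topologies(labels)
    edges = tops[int(rng.integers(0, len(tops)))]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            path = _path_edges(edges, labels[i], labels[j])
            dist[i, j] = dist[j, i] = lengths[path].sum()
    return dist, bipartition_set(edges, labels)
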