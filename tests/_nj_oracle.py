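"""Independent neighbor-joining oracle: exhaustive least-squares topology fit.

Enumerates every unrooted binary topology over n taxa (3 for n=4, 15 for
n=5), least-squares-fits branch lengths to the distance matrix via the
edge-path design matrix, and declares the generating topology to be the one
with (numerically) zero residual. Shares no code with the package's NJ
implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_topologies(labels):
    """All unrooted binary topologies as adjacency dicts {node: set(neighbors)}.

    Leaves are the labels; internal nodes are negative ints. Built by
    sequential taxon insertion into every edge.
    """
    labels = list(labels)
    assert len(labels) >= 3
    base = {labels[0]: {-1}, labels[1]: {-1}, labels[2]: {-1},
            -1: {labels[0], labels[1], labels[2]}}
    trees = [base]
    next_internal = -2
    for leaf in labels[3:]:
        new_trees = []
        for t in trees:
            for u, v in _edges(t):
                nt = {k: set(vs) for k, vs in t.items()}
                w = next_internal
                nt[u].discard(v)
                nt[v].discard(u)
                nt[u].add(w)
                nt[v].add(w)
                nt[w] = {u, v, leaf}
                nt[leaf] = {w}
                new_trees.append(nt)
        trees = new_trees
        next_internal -= 1
    return trees


def _edges(adj):
    seen = set()
    for u, vs in adj.items():
        for v in vs:
            key = (u, v) if str(u) < str(v) else (v, u)
            if key not in seen:
                seen.add(key)
                yield key


def _path_edges(adj, a, b):
    """Edges on the unique path from leaf a to leaf b."""
    stack = [(a, None, [])]
    while stack:
        node, parent, path = stack.pop()
        if node == b:
            return path
        for nbr in adj[node]:
            if nbr != parent:
                key = (node, nbr) if str(node) < str(nbr) else (nbr, node)
                stack.append((nbr, node, path + [key]))
    raise AssertionError("leaves not connected")


def bipartitions(adj, labels):
    """Canonical internal bipartitions of a topology (frozenset not holding
    the lexicographically first label)."""
    labels = set(labels)
    ref = min(labels)
    out = set()
    for u, v in _edges(adj):
        side = _leaves_behind(adj, v, u, labels)
        if 2 <= len(side) <= len(labels) - 2:
            out.add(frozenset(labels - side) if ref in side else frozenset(side))
    return out


def _leaves_behind(adj, node, parent, labels):
    out = set()
    stack = [(node, parent)]
    while stack:
        u, p = stack.pop()
        if u in labels:
            out.add(u)
        for v in adj[u]:
            if v != p:
                stack.append((v, u))
    return out


def ls_fit(adj, labels, D):
    """Least-squares branch lengths for one topology; returns (residual, lengths)."""
    edges = list(_edges(adj))
    idx = {e: i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for e in _path_edges(adj, labels[i], labels[j]):
            A[r, idx[e]] = 1.0
        y[r] = D[i, j]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    residual = float(np.linalg.norm(A @ lengths - y))
    return residual, dict(zip(edges, lengths))


def best_topology(labels, D):
    """The exact-fit topology's bipartition set (asserts a unique zero-residual fit)."""
    fits = []
    for adj in enumerate_topologies(labels):
        residual, _ = ls_fit(adj, labels, D)
        fits.append((residual, adj))
    fits.sort(key=lambda x: x[0])
    best_res, best_adj = fits[0]
    assert best_res < 1e-8, f"no additive topology fits (best residual {best_res})"
    return bipartitions(best_adj, labels)


def random_additive_matrix(labels, rng):
    """Distances from a random unrooted binary tree with uniform(0.05, 1) branches.

    Returns (D, truth bipartition set).
    """
    topologies = enumerate_topologies(labels)
    adj = topologies[int(rng.integers(0, len(topologies)))]
    lengths = {e: float(rng.uniform(0.05, 1.0)) for e in _edges(adj)}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(lengths[e] for e in _path_edges(adj, labels[i], labels[j]))
            D[i, j] = D[j, i] = d
    return D, bipartitions(adj, labels)
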