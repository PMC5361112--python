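"""Clade assignment by neighbor joining with bootstrap support.

New consensus mitogenomes are classified into named clades/haplogroups by
their similarity and phylogenetic grouping with labeled published
haplotypes: pairwise distances are computed over the shared alignment, a
neighbor-joining tree is built (Saitou-Nei agglomeration, implemented from
the standard recurrences), internal edges receive bootstrap support from
column-resampled replicates (100 by default), and each query inherits the
clade label of the smallest well-supported group that contains it together
with labeled references of a single clade.

Distances are uncorrected p-distances with pairwise deletion (sites where
either sequence has an N or gap are excluded for that pair) — the minimal
assumption, adequate at intraspecific divergence; a Jukes-Cantor correction
is available behind the ``model`` flag. Negative NJ branch-length estimates
are clamped to zero with the deficit transferred to the sibling branch, the
standard practice. Ties in the Q-matrix minimisation are broken by
lexicographic taxon-pair order so the tree is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_VALID = frozenset(b"ACGT")

UNASSIGNED = "unassigned"


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    distances: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        n = len(self.labels)
        self.distances = np.asarray(self.distances, dtype=float)
        self.comparable_sites = np.asarray(self.comparable_sites, dtype=np.int64)
        if self.distances.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(self.distances, self.distances.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.distances) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.distances[i, j])


def compute_distances(alignment: dict[str, str], model: str = "p") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion over an equal-length alignment.

    For each pair only sites where both sequences carry an unambiguous base
    (A/C/G/T) are compared; N and ``-`` are excluded. ``model="p"`` gives the
    uncorrected mismatch proportion, ``model="jc"`` the Jukes-Cantor
    correction ``-3/4 ln(1 - 4p/3)``.
    """
    if model not in ("p", "jc"):
        raise ValueError("model must be 'p' or 'jc'")
    labels = tuple(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    arrs = [np.frombuffer(alignment[l].upper().encode(), dtype=np.uint8) for l in labels]
    valid = [np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for a in arrs]
    n = len(labels)
    dist = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        comp[i, i] = int(valid[i].sum())
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((arrs[i][both] != arrs[j][both]).sum()) / m
            if model == "jc":
                if p >= 0.75:
                    raise ValueError(
                        f"p-distance {p:.3f} between {labels[i]!r} and {labels[j]!r} "
                        "exceeds the Jukes-Cantor limit of 3/4"
                    )
                p = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = p
            comp[i, j] = comp[j, i] = m
    return DistanceMatrix(labels, dist, comp)


@dataclass
class CladeTree:
    """An unrooted binary tree with branch lengths and bipartition supports.

    ``adjacency[u][v]`` is the length of edge (u, v); ``leaf_labels`` maps
    leaf node ids to taxon labels; ``supports`` maps canonical internal
    bipartitions (frozenset of the taxa on the side not containing the
    lexicographically first taxon) to percentages in [0, 100].
    """

    adjacency: dict[int, dict[int, float]]
    leaf_labels: dict[int, str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_clamped_branches: int = 0

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.leaf_labels.values())

    def _leaves_behind(self, node: int, parent: int) -> frozenset:
        """Leaf labels reachable from ``node`` when the edge to ``parent`` is cut."""
        out = []
        stack = [(node, parent)]
        while stack:
            u, p = stack.pop()
            if u in self.leaf_labels:
                out.append(self.leaf_labels[u])
            for v in self.adjacency[u]:
                if v != p:
                    stack.append((v, u))
        return frozenset(out)

    def _canonical(self, side: frozenset) -> frozenset:
        ref = min(self.taxa)
        return self.taxa - side if ref in side else side

    def bipartitions(self) -> dict[frozenset, tuple[int, int]]:
        """Canonical internal bipartitions → one representative edge."""
        all_taxa = self.taxa
        out: dict[frozenset, tuple[int, int]] = {}
        seen = set()
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                side = self._leaves_behind(v, u)
                if 2 <= len(side) <= len(all_taxa) - 2:
                    out[self._canonical(side)] = (u, v)
        return out

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the leaf-to-leaf path."""
        ids = {lab: i for i, lab in self.leaf_labels.items()}
        start, goal = ids[a], ids[b]
        stack = [(start, -1, 0.0)]
        while stack:
            u, p, acc = stack.pop()
            if u == goal:
                return acc
            for v, w in self.adjacency[u].items():
                if v != p:
                    stack.append((v, u, acc + w))
        raise ValueError(f"no path between {a!r} and {b!r}")

    def to_newick(self) -> str:
        """Newick with bootstrap supports as internal node labels."""
        root = max(self.adjacency)  # last internal node created

        def render(u: int, parent: int) -> str:
            if u in self.leaf_labels:
                return self.leaf_labels[u]
            parts = [
                f"{render(v, u)}:{w:.6g}"
                for v, w in sorted(self.adjacency[u].items())
                if v != parent
            ]
            label = ""
            if parent >= 0:
                side = self._leaves_behind(u, parent)
                if 2 <= len(side) <= len(self.taxa) - 2:
                    sup = self.supports.get(self._canonical(side))
                    if sup is not None:
                        label = f"{sup:g}"
            return f"({','.join(parts)}){label}"

        return render(root, -1) + ";"


def nj_tree(D: DistanceMatrix) -> CladeTree:
    """Neighbor joining (Saitou-Nei) on a distance matrix.

    Exact on additive matrices: leaf-to-leaf path lengths in the returned
    tree reproduce the input distances. Deterministic: Q-ties are broken by
    the lexicographically smallest taxon pair.
    """
    labels = list(D.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    dist: dict[int, dict[int, float]] = {
        i: {j: float(D.distances[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = dict(enumerate(labels))
    # sort key of an active node: the smallest taxon label beneath it
    keys = dict(enumerate(labels))
    active = list(range(n))
    next_id = n
    n_clamped = 0

    def attach(u: int, v: int, w: float) -> None:
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i][j] for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for i in active:
            for j in active:
                if i >= j:
                    continue
                q = (m - 2) * dist[i][j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key)
                if best is None or cand < best:
                    best = cand
                    best_pair = (i, j)
        i, j = best_pair
        dij = dist[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
            n_clamped += 1
        elif lj < 0:
            li, lj = dij, 0.0
            n_clamped += 1
        u = next_id
        next_id += 1
        attach(u, i, li)
        attach(u, j, lj)
        keys[u] = min(keys[i], keys[j])
        dist[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist[i][k] + dist[j][k] - dij)
            dist[u][k] = dist[k][u] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda x: keys[x])
    dab, dac, dbc = dist[a][b], dist[a][c], dist[b][c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    clamped = sum(1 for x in (la, lb, lc) if x < 0)
    n_clamped += clamped
    center = next_id
    attach(center, a, max(la, 0.0))
    attach(center, b, max(lb, 0.0))
    attach(center, c, max(lc, 0.0))
    return CladeTree(
        adjacency=adjacency,
        leaf_labels=leaf_labels,
        n_clamped_branches=n_clamped,
    )


def bootstrap_support(
    alignment: dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "p",
) -> CladeTree:
    """NJ tree from the full alignment, internal edges annotated with the
    percentage of column-resampled replicate trees containing the same
    bipartition. Deterministic given ``seed``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(compute_distances(alignment, model=model))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    labels = list(alignment)
    length = len(next(iter(alignment.values())))
    arrs = {l: np.frombuffer(alignment[l].encode(), dtype=np.uint8) for l in labels}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {l: arrs[l][cols].tobytes().decode() for l in labels}
        rep = nj_tree(compute_distances(resampled, model=model))
        rep_bps = rep.bipartitions().keys()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    return tree


@dataclass
class CladeAssignment:
    query: str
    clade: str  # a reference clade label or "unassigned"
    support: float | None
    nearest_label: str
    nearest_distance: float


def assign_clade(
    tree: CladeTree,
    reference_labels: dict[str, str],
    min_support: float = 70.0,
    distances: DistanceMatrix | None = None,
) -> list[CladeAssignment]:
    """Assign every unlabeled leaf a clade by supported phylogenetic grouping.

    A query is assigned clade X iff the smallest supported internal edge
    (support >= ``min_support``) that groups the query with at least one
    labeled taxon has only clade-X labels on the query's side; any label
    conflict or absence of such an edge yields "unassigned". The nearest
    labeled neighbor (by alignment distance if given, else tree path length)
    is reported for every query.
    """
    taxa = tree.taxa
    labeled = {t: c for t, c in reference_labels.items() if t in taxa}
    if not labeled:
        raise ValueError("tree contains no labeled reference taxa")
    queries = sorted(taxa - labeled.keys())

    # sides of each supported internal edge, from the canonical bipartitions
    sides: list[tuple[frozenset, float]] = []
    for bp, edge in tree.bipartitions().items():
        sup = tree.supports.get(bp)
        if sup is None or sup < min_support:
            continue
        sides.append((bp, sup))
        sides.append((taxa - bp, sup))

    def nearest(query: str) -> tuple[str, float]:
        if distances is not None:
            pairs = [(distances.get(query, t), t) for t in sorted(labeled)]
        else:
            pairs = [(tree.path_length(query, t), t) for t in sorted(labeled)]
        d, t = min(pairs)
        return t, d

    out = []
    for q in queries:
        near_t, near_d = nearest(q)
        candidates = [
            (len(side), side, sup)
            for side, sup in sides
            if q in side and any(t in labeled for t in side)
        ]
        clade = UNASSIGNED
        support = None
        if candidates:
            _, side, sup = min(candidates, key=lambda x: (x[0], sorted(x[1])))
            clades = {labeled[t] for t in side if t in labeled}
            if len(clades) == 1:
                clade = clades.pop()
                support = sup
        out.append(
            CladeAssignment(
                query=q,
                clade=clade,
                support=support,
                nearest_label=near_t,
                nearest_distance=near_d,
            )
        )
    return out


def assign_clades(
    alignment: dict[str, str],
    reference_labels: dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
    min_support: float = 70.0,
    model: str = "p",
) -> tuple[list[CladeAssignment], CladeTree]:
    """End-to-end: distances → NJ + bootstrap → clade assignment."""
    D = compute_distances(alignment, model=model)
    tree = bootstrap_support(alignment, n_replicates=n_replicates, seed=seed, model=model)
    return assign_clade(tree, reference_labels, min_support=min_support, distances=D), tree
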