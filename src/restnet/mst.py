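"""Minimum-spanning-tree backbone of a coherence network and its metrics.

The MST is computed on inverse-weight distances d = 1/w, so it is the
maximum-coherence spanning tree: the unique acyclic backbone of strongest
connections (unique when weights are distinct; ties are broken by
lexicographic edge order for reproducibility).

Betweenness centrality follows the unnormalized ordered-pair convention:
BC(v) counts ordered pairs (s, u), s != u != v, whose unique tree path
passes through v. On a tree this is exactly twice the unordered count, and
its ceiling is (n-1)(n-2) — 6806 for the 84-node star.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from restnet.graph import validate_adjacency


@dataclass(frozen=True)
class SpanningTree:
    """Acyclic connected binary subgraph with n-1 edges.

    Attributes
    ----------
    n : int
        Node count.
    edges : tuple of (int, int)
        Unordered node pairs ``(i, j)`` with ``i < j``, sorted.
    node_labels : tuple of str, optional
        ROI labels in node order.
    """

    n: int
    edges: tuple[tuple[int, int], ...]
    node_labels: tuple[str, ...] | None = None
    _adj: tuple[tuple[int, ...], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.edges) != self.n - 1:
            raise ValueError(
                f"a spanning tree on {self.n} nodes needs {self.n - 1} edges, "
                f"got {len(self.edges)}"
            )
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            if not (0 <= i < j < self.n):
                raise ValueError(f"bad edge ({i}, {j}) for n={self.n}")
            adj[i].append(j)
            adj[j].append(i)
        # n-1 edges + connected => acyclic; verify connectivity by BFS
        seen = np.zeros(self.n, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(u)
        if not seen.all():
            raise ValueError("edge set does not span all nodes")
        object.__setattr__(self, "_adj", tuple(tuple(a) for a in adj))

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self._adj])


@dataclass(frozen=True)
class TreeMetrics:
    """The tree statistics for one subject/band."""

    bc: np.ndarray  # ordered-pair betweenness per node
    max_bc: int
    degree: np.ndarray
    leaf_fraction: float
    diameter: int
    eccentricity: np.ndarray
    avg_eccentricity: float

    def to_dict(self) -> dict:
        return {
            "max_bc": self.max_bc,
            "leaf_fraction": self.leaf_fraction,
            "diameter": self.diameter,
            "avg_eccentricity": self.avg_eccentricity,
            "bc": self.bc.tolist(),
            "degree": self.degree.tolist(),
            "eccentricity": self.eccentricity.tolist(),
        }


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(
    W: np.ndarray, node_labels: tuple[str, ...] | None = None
) -> SpanningTree:
    """MST of the distance graph d = 1/w (maximum-coherence spanning tree).

    Kruskal's algorithm with edges sorted by (distance, i, j); the
    lexicographic key makes the tree deterministic when coherences tie.
    """
    W = validate_adjacency(W)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    present = w > 0
    iu, ju, w = iu[present], ju[present], w[present]
    order = np.lexsort((ju, iu, 1.0 / w))
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    for idx in order:
        if uf.union(int(iu[idx]), int(ju[idx])):
            edges.append((int(iu[idx]), int(ju[idx])))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValueError("graph is disconnected; no spanning tree exists")
    return SpanningTree(n=n, edges=tuple(sorted(edges)), node_labels=node_labels)


def _subtree_sizes(t: SpanningTree, root: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Iterative DFS giving parent and subtree size per node."""
    parent = np.full(t.n, -1, dtype=int)
    order: list[int] = []
    stack = [root]
    visited = np.zeros(t.n, dtype=bool)
    visited[root] = True
    while stack:
        v = stack.pop()
        order.append(v)
        for u in t._adj[v]:
            if not visited[u]:
                visited[u] = True
                parent[u] = v
                stack.append(u)
    size = np.ones(t.n, dtype=int)
    for v in reversed(order):
        if parent[v] >= 0:
            size[parent[v]] += size[v]
    return parent, size


def betweenness_centrality(t: SpanningTree) -> np.ndarray:
    """Ordered-pair betweenness: for each node v, the number of ordered
    pairs (s, u) with s != u != v whose unique tree path passes through v.

    Removing v splits the tree into components of sizes s_1..s_k; the count
    is sum_{a != b} s_a s_b = (n-1)^2 - sum s_a^2.
    """
    parent, size = _subtree_sizes(t)
    n = t.n
    bc = np.zeros(n, dtype=np.int64)
    for v in range(n):
        comp_sq = 0
        for u in t._adj[v]:
            s = size[u] if parent[u] == v else n - size[v]
            comp_sq += s * s
        bc[v] = (n - 1) ** 2 - comp_sq
    return bc


def leaf_fraction(t: SpanningTree) -> float:
    """Number of degree-1 nodes divided by n - 1 (star = 1, long path -> 0)."""
    if t.n < 2:
        raise ValueError("leaf fraction needs at least 2 nodes")
    return float(np.count_nonzero(t.degrees == 1)) / (t.n - 1)


def eccentricity_and_diameter(
    t: SpanningTree,
) -> tuple[np.ndarray, float, int]:
    """Per-node eccentricity (in edges), its mean, and the tree diameter."""
    n = t.n
    ecc = np.zeros(n, dtype=int)
    for s in range(n):
        dist = np.full(n, -1, dtype=int)
        dist[s] = 0
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for u in t._adj[v]:
                    if dist[u] < 0:
                        dist[u] = dist[v] + 1
                        nxt.append(u)
            frontier = nxt
        ecc[s] = dist.max()
    return ecc, float(ecc.mean()), int(ecc.max())


def tree_metrics(t: SpanningTree) -> TreeMetrics:
    """Aggregate betweenness, degree, leaf fraction, diameter, eccentricity."""
    bc = betweenness_centrality(t)
    ecc, avg_ecc, diam = eccentricity_and_diameter(t)
    return TreeMetrics(
        bc=bc,
        max_bc=int(bc.max()),
        degree=t.degrees,
        leaf_fraction=leaf_fraction(t),
        diameter=diam,
        eccentricity=ecc,
        avg_eccentricity=avg_ecc,
    )
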