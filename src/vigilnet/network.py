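"""MST backbone of a connectivity matrix and tree topology metrics.

The "minimum spanning tree" of a functional connectivity matrix retains the
n-1 *strongest* connections that span all n nodes, i.e. it is the
maximum-weight spanning tree (equivalently, the minimum spanning tree on
reciprocal or negated weights).  For 78 ROIs the backbone always has 77
edges, which removes any thresholding arbitrariness when comparing states.

Tree metrics:

* leaf number L -- count of degree-1 nodes; between 2 (path) and n-1 (star);
* leaf fraction Lf = L / (n-1);
* betweenness centrality bc(u) -- fraction of unordered node pairs (u not an
  endpoint) whose unique tree path passes through u, normalized by
  (n-1)(n-2)/2 so that a star's hub scores exactly 1 and every leaf 0;
* tree hierarchy Th = L / (2 * M * bc_max) with M = n-1, balancing
  integration (many leaves) against hub overload (high bc_max): exactly 0.5
  for a star, tending to 0 for a long path.

Kruskal's algorithm with a deterministic tie rule (descending weight, then
lexicographic edge order) makes the extracted tree reproducible even for
degenerate weight ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ArgumentError, VigilnetError
from .connectivity import ConnectivityMatrix


class DisconnectedGraphError(VigilnetError):
    """The positive-weight graph does not span all nodes."""


@dataclass
class Tree:
    """A spanning tree: ``n`` nodes, ``n - 1`` unordered edges."""

    n: int
    edges: list[tuple[int, int]]
    source: ConnectivityMatrix | None = None

    def __post_init__(self) -> None:
        if len(self.edges) != self.n - 1:
            raise ArgumentError(
                f"a tree on {self.n} nodes needs {self.n - 1} edges, "
                f"got {len(self.edges)}"
            )
        self.edges = [(min(i, j), max(i, j)) for i, j in self.edges]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj


@dataclass
class MSTSummary:
    """Global topology metrics of one spanning tree."""

    leaf_number: int
    leaf_fraction: float
    tree_hierarchy: float
    bc: np.ndarray
    bc_max: float
    tree: Tree | None = field(default=None, repr=False)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def mst_from_connectivity(m: ConnectivityMatrix | np.ndarray) -> Tree:
    """Maximum-weight spanning tree of a symmetric connectivity matrix.

    Kruskal over edges sorted by descending weight, ties broken by
    lexicographic (i, j) order.  Zero-weight edges carry no connection;
    if the positive-weight graph is disconnected a
    :class:`DisconnectedGraphError` is raised.
    """
    source = m if isinstance(m, ConnectivityMatrix) else None
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    n = values.shape[0]
    if values.shape != (n, n):
        raise ArgumentError("connectivity matrix must be square")
    if n < 2:
        raise ArgumentError("need at least 2 nodes")
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ArgumentError("off-diagonal weights must be finite and >= 0")
    pos = w > 0
    order = np.lexsort((ju[pos], iu[pos], -w[pos]))
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    for k in order:
        i, j = int(iu[pos][k]), int(ju[pos][k])
        if uf.union(i, j):
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise DisconnectedGraphError(
            f"positive-weight graph spans only part of the {n} nodes"
        )
    return Tree(n=n, edges=edges, source=source)


def leaf_metrics(t: Tree) -> tuple[int, float]:
    """Leaf number L (degree-1 nodes) and leaf fraction Lf = L/(n-1)."""
    deg = t.degrees()
    leaf_number = int(np.sum(deg == 1))
    return leaf_number, leaf_number / (t.n - 1)


def _subtree_sizes(t: Tree) -> tuple[list[int], list[int], np.ndarray]:
    """Root the tree at node 0; return (preorder, parent, subtree_size)."""
    adj = t.adjacency()
    parent = [-1] * t.n
    order: list[int] = []
    stack = [0]
    seen = [False] * t.n
    seen[0] = True
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    size = np.ones(t.n, dtype=np.int64)
    for u in reversed(order):
        if parent[u] >= 0:
            size[parent[u]] += size[u]
    return order, parent, size


def betweenness(t: Tree) -> tuple[np.ndarray, float]:
    """Normalized betweenness centrality of every node, and its maximum.

    In a tree the path between any two nodes is unique, so bc(u) is the
    number of node pairs whose path transits u (endpoints excluded) divided
    by (n-1)(n-2)/2.  Computed in O(n) from subtree sizes: deleting u splits
    the tree into components of sizes s_1..s_k, and the transiting pairs are
    the pairs with endpoints in two different components.
    """
    n = t.n
    if n < 3:
        # with fewer than 3 nodes no pair can transit a third node
        return np.zeros(n), 0.0
    order, parent, size = _subtree_sizes(t)
    adj = t.adjacency()
    total_pairs = (n - 1) * (n - 2) / 2
    bc = np.zeros(n)
    for u in range(n):
        comp = [size[v] for v in adj[u] if parent[v] == u]
        if parent[u] >= 0:
            comp.append(n - size[u])
        comp = np.asarray(comp, dtype=float)
        passing = (comp.sum() ** 2 - (comp ** 2).sum()) / 2
        bc[u] = passing / total_pairs
    return bc, float(bc.max())


def tree_hierarchy(t: Tree) -> float:
    """Tree hierarchy Th = L / (2 M bc_max), M = n - 1.

    Exactly 0.5 for a star (L = M, bc_max = 1); tends to 0 for a path as n
    grows.  Undefined below 3 nodes.
    """
    if t.n < 3:
        raise ArgumentError("tree hierarchy needs at least 3 nodes")
    leaf_number, _ = leaf_metrics(t)
    _, bc_max = betweenness(t)
    return leaf_number / (2 * (t.n - 1) * bc_max)


def summarize_tree(t: Tree) -> MSTSummary:
    """All global topology metrics of one tree."""
    leaf_number, leaf_fraction = leaf_metrics(t)
    bc, bc_max = betweenness(t)
    th = (
        leaf_number / (2 * (t.n - 1) * bc_max)
        if t.n >= 3 and bc_max > 0
        else float("nan")
    )
    return MSTSummary(
        leaf_number=leaf_number,
        leaf_fraction=leaf_fraction,
        tree_hierarchy=th,
        bc=bc,
        bc_max=bc_max,
        tree=t,
    )


def star_tree(n: int, center: int = 0) -> Tree:
    """A star on ``n`` nodes with the given hub."""
    return Tree(n=n, edges=[(center, j) for j in range(n) if j != center])


def path_tree(n: int) -> Tree:
    """A path 0-1-...-(n-1)."""
    return Tree(n=n, edges=[(i, i + 1) for i in range(n - 1)])
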