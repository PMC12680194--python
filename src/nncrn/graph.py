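"""Undirected simple-graph container tuned for edge-rewiring Markov chains.

The rewiring chains need three things a general-purpose graph library does
not provide together: O(1) uniform sampling of ordered edges, in-place
degree-preserving double-edge swaps, and enumeration of node pairs at an
exact shortest-path distance.  This module owns that data structure; for
interoperability (GraphML, k-cores) graphs convert to/from networkx.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Graph",
    "DegreeEdgeBuckets",
    "SwapOutcome",
    "swap_edges",
    "neighbors_at_distance",
    "distance_pairs",
]


@dataclass(frozen=True)
class SwapOutcome:
    """Result of attempting a double-edge swap.

    ``applied`` is True when the graph was modified.  Otherwise ``reason``
    is one of ``"self-loop"``, ``"multi-edge"`` or ``"no-op"`` (the proposed
    replacement would leave the edge set unchanged — the chains treat this
    as a rejection that still consumes a time step).
    """

    applied: bool
    reason: str | None = None


class Graph:
    """Simple undirected graph on nodes ``0..N-1``.

    Maintains adjacency sets, a positional edge array supporting O(1)
    uniform indexing, and an edge→position map so that double-edge swaps
    run in O(1) expected time.  No self-loops, no parallel edges.
    """

    __slots__ = ("_adj", "_edges", "_pos")

    def __init__(self, n_nodes: int, edges: Iterable[tuple[int, int]] = ()):
        if n_nodes < 0:
            raise ValueError("node count must be nonnegative")
        self._adj: list[set[int]] = [set() for _ in range(n_nodes)]
        self._edges: list[tuple[int, int]] = []
        self._pos: dict[tuple[int, int], int] = {}
        for u, v in edges:
            self.add_edge(u, v)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def degrees(self) -> np.ndarray:
        """Degree of every node, as an int64 array indexed by node id."""
        return np.array([len(s) for s in self._adj], dtype=np.int64)

    def neighbors(self, v: int) -> set[int]:
        """The adjacency set of ``v`` (live view — do not mutate)."""
        self._check_node(v)
        return self._adj[v]

    def has_edge(self, u: int, v: int) -> bool:
        self._check_node(u)
        self._check_node(v)
        return v in self._adj[u]

    def edges(self) -> list[tuple[int, int]]:
        """All edges, one canonical ``(min, max)`` tuple each."""
        return list(self._edges)

    def edge_at(self, index: int) -> tuple[int, int]:
        return self._edges[index]

    def add_edge(self, u: int, v: int) -> None:
        self._check_node(u)
        self._check_node(v)
        if u == v:
            raise ValueError(f"self-loop at node {u} not allowed")
        key = (u, v) if u < v else (v, u)
        if key in self._pos:
            raise ValueError(f"duplicate edge {key}")
        self._pos[key] = len(self._edges)
        self._edges.append(key)
        self._adj[u].add(v)
        self._adj[v].add(u)

    def copy(self) -> "Graph":
        g = Graph(self.n_nodes)
        g._edges = list(self._edges)
        g._pos = dict(self._pos)
        g._adj = [set(s) for s in self._adj]
        return g

    def _check_node(self, v: int) -> None:
        if not (0 <= v < len(self._adj)):
            raise KeyError(f"unknown node id {v}")

    # -- sampling ----------------------------------------------------------

    def sample_ordered_edge(self, rng: np.random.Generator) -> tuple[int, int]:
        """Draw an ordered edge uniformly: uniform unordered edge, then a
        uniform orientation (each of the 2M ordered edges has mass 1/2M)."""
        if not self._edges:
            raise ValueError("graph has no edges")
        u, v = self._edges[int(rng.integers(len(self._edges)))]
        return (u, v) if rng.integers(2) == 0 else (v, u)

    # -- double-edge swap --------------------------------------------------

    def classify_swap(
        self, e1: tuple[int, int], e2: tuple[int, int]
    ) -> str | None:
        """Reason the swap ``(u1,u2),(v1,v2) -> (u1,v2),(v1,u2)`` would be
        rejected, or None when it is admissible.  Raises if either ordered
        edge is not currently present (distinct from rejection)."""
        u1, u2 = e1
        v1, v2 = e2
        if not self.has_edge(u1, u2):
            raise ValueError(f"edge {e1} not in graph")
        if not self.has_edge(v1, v2):
            raise ValueError(f"edge {e2} not in graph")
        if {u1, u2} == {v1, v2}:
            # same unordered edge drawn twice
            return "no-op" if (u1, u2) == (v1, v2) else "self-loop"
        if u1 == v1 or u2 == v2:
            return "no-op"  # replacement equals the current edge set
        if u1 == v2 or v1 == u2:
            return "self-loop"
        if v2 in self._adj[u1] or u2 in self._adj[v1]:
            return "multi-edge"
        return None

    def swap_edges(
        self, e1: tuple[int, int], e2: tuple[int, int]
    ) -> SwapOutcome:
        """Attempt the double-edge swap ``(u1,u2),(v1,v2) -> (u1,v2),(v1,u2)``.

        Degrees of all nodes are preserved.  On rejection the graph is left
        unmodified and the outcome carries the reason.
        """
        reason = self.classify_swap(e1, e2)
        if reason is not None:
            return SwapOutcome(False, reason)
        u1, u2 = e1
        v1, v2 = e2
        k1 = (u1, u2) if u1 < u2 else (u2, u1)
        k2 = (v1, v2) if v1 < v2 else (v2, v1)
        i1 = self._pos.pop(k1)
        i2 = self._pos.pop(k2)
        n1 = (u1, v2) if u1 < v2 else (v2, u1)
        n2 = (v1, u2) if v1 < u2 else (u2, v1)
        self._edges[i1] = n1
        self._edges[i2] = n2
        self._pos[n1] = i1
        self._pos[n2] = i2
        self._adj[u1].remove(u2)
        self._adj[u2].remove(u1)
        self._adj[v1].remove(v2)
        self._adj[v2].remove(v1)
        self._adj[u1].add(v2)
        self._adj[v2].add(u1)
        self._adj[v1].add(u2)
        self._adj[u2].add(v1)
        return SwapOutcome(True)

    # -- conversions -------------------------------------------------------

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR adjacency ``(indptr, data)`` used by the jit kernels.

        ``data[indptr[v]:indptr[v+1]]`` lists the neighbors of ``v``; slot
        order within a node is arbitrary.
        """
        deg = self.degrees()
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        np.cumsum(deg, out=indptr[1:])
        data = np.empty(int(indptr[-1]), dtype=np.int64)
        fill = indptr[:-1].copy()
        for u, v in self._edges:
            data[fill[u]] = v
            fill[u] += 1
            data[fill[v]] = u
            fill[v] += 1
        return indptr, data

    @classmethod
    def from_arrays(cls, indptr: np.ndarray, data: np.ndarray) -> "Graph":
        n = len(indptr) - 1
        g = cls(n)
        for u in range(n):
            for j in range(int(indptr[u]), int(indptr[u + 1])):
                v = int(data[j])
                if u < v:
                    g.add_edge(u, v)
        return g

    def to_networkx(self):
        import networkx as nx

        gx = nx.Graph()
        gx.add_nodes_from(range(self.n_nodes))
        gx.add_edges_from(self._edges)
        return gx

    @classmethod
    def from_networkx(cls, gx) -> tuple["Graph", list]:
        """Convert, relabeling arbitrary node labels to 0..N-1.

        Returns the graph and the label list (``labels[i]`` is the original
        label of internal node ``i``).
        """
        labels = sorted(gx.nodes(), key=lambda x: (str(type(x)), x))
        index = {lab: i for i, lab in enumerate(labels)}
        g = cls(len(labels))
        for a, b in gx.edges():
            if a == b:
                continue
            g.add_edge(index[a], index[b])
        return g, labels

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(N={self.n_nodes}, M={self.n_edges})"


class DegreeEdgeBuckets:
    """Index of ordered edges grouped by the degree of their source node.

    Because double-edge swaps never change any node's degree, a node of
    degree ``d`` always contributes exactly ``d`` ordered edges to the
    degree-``d`` bucket.  Drawing a uniform node among those of degree
    ``d`` and then a uniform neighbor of it is therefore an exactly
    uniform draw over the bucket — the index is static and needs no
    maintenance across swaps.
    """

    def __init__(self, g: Graph):
        deg = g.degrees()
        self._graph = g
        self._nodes_by_degree: dict[int, np.ndarray] = {
            int(d): np.flatnonzero(deg == d).astype(np.int64)
            for d in np.unique(deg)
        }

    def count(self, d: int) -> int:
        """Number of ordered edges whose source has degree ``d``."""
        nodes = self._nodes_by_degree.get(d)
        return 0 if nodes is None else d * len(nodes)

    def total(self) -> int:
        """Total bucket size; always equals 2M."""
        return sum(self.count(d) for d in self._nodes_by_degree)

    def sample(self, d: int, rng: np.random.Generator) -> tuple[int, int]:
        """Uniform ordered edge ``(v1, v2)`` with ``degree(v1) == d``."""
        nodes = self._nodes_by_degree.get(d)
        if nodes is None or d == 0:
            raise ValueError(f"no ordered edges with source degree {d}")
        v1 = int(nodes[int(rng.integers(len(nodes)))])
        nbrs = tuple(self._graph.neighbors(v1))
        v2 = int(nbrs[int(rng.integers(len(nbrs)))])
        return v1, v2

    def ordered_edges(self, d: int) -> Iterator[tuple[int, int]]:
        for v1 in self._nodes_by_degree.get(d, ()):
            for v2 in self._graph.neighbors(int(v1)):
                yield int(v1), int(v2)

    def check_consistent(self, g: Graph) -> bool:
        deg = g.degrees()
        for d, nodes in self._nodes_by_degree.items():
            if not np.array_equal(np.flatnonzero(deg == d), np.sort(nodes)):
                return False
        return self.total() == 2 * g.n_edges


# -- distances -------------------------------------------------------------


def _bfs_levels(g: Graph, source: int, cutoff: int | None = None) -> dict[int, int]:
    """Shortest-path distance from ``source`` to every reachable node,
    optionally truncated at ``cutoff``."""
    dist = {source: 0}
    frontier = deque([source])
    while frontier:
        u = frontier.popleft()
        du = dist[u]
        if cutoff is not None and du >= cutoff:
            continue
        for w in g.neighbors(u):
            if w not in dist:
                dist[w] = du + 1
                frontier.append(w)
    return dist


def neighbors_at_distance(g: Graph, v: int, l: int) -> set[int]:
    """Nodes at shortest-path distance exactly ``l`` from ``v``.

    ``l = 0`` returns ``{v}``; nodes in other components never appear.
    """
    g._check_node(v)
    if l < 0:
        raise ValueError("distance must be nonnegative")
    dist = _bfs_levels(g, v, cutoff=l)
    return {w for w, d in dist.items() if d == l}


def distance_pairs(g: Graph, l: int) -> tuple[list[tuple[int, int]], int]:
    """All unordered node pairs at shortest-path distance exactly ``l``.

    Each pair appears once regardless of how many shortest paths realize
    the distance; pairs in different components are excluded.  Returns
    ``(pairs, M(l))`` where ``M(l)`` is the pair count.
    """
    if l < 1:
        raise ValueError("distance must be >= 1")
    if l == 1:
        pairs = g.edges()
        return pairs, len(pairs)
    pairs = []
    for u in range(g.n_nodes):
        for w in neighbors_at_distance(g, u, l):
            if w > u:
                pairs.append((u, w))
    return pairs, len(pairs)


def swap_edges(g: Graph, e1: tuple[int, int], e2: tuple[int, int]) -> SwapOutcome:
    """Module-level alias of :meth:`Graph.swap_edges`."""
    return g.swap_edges(e1, e2)
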