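"""Plain-text edge-list and GraphML input/output.

Edge lists: two whitespace-separated integer node ids per line, one
undirected edge per line, ``#``-prefixed comments.  Arbitrary integer
labels are relabeled to contiguous 0-based ids on load and the mapping is
returned alongside the graph (and restored on write when provided).
"""

from __future__ import annotations

import os

from .graph import Graph

__all__ = ["read_edgelist", "write_edgelist", "read_graphml", "write_graphml"]


def read_edgelist(path: str | os.PathLike) -> tuple[Graph, list[int]]:
    """Load an edge list.

    Returns ``(graph, labels)`` where ``labels[i]`` is the original label
    of internal node ``i``.  Duplicate lines and self-loops are rejected.
    """
    raw_edges: list[tuple[int, int]] = []
    labels_seen: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two integer columns, got {body!r}"
                )
            a, b = int(parts[0]), int(parts[1])
            raw_edges.append((a, b))
            labels_seen.update((a, b))
    labels = sorted(labels_seen)
    index = {lab: i for i, lab in enumerate(labels)}
    g = Graph(len(labels))
    for a, b in raw_edges:
        g.add_edge(index[a], index[b])
    return g, labels


def write_edgelist(
    g: Graph, path: str | os.PathLike, labels: list[int] | None = None
) -> None:
    """Write each edge once, two columns, optionally restoring labels."""
    with open(path, "w") as fh:
        fh.write(f"# nodes {g.n_nodes} edges {g.n_edges}\n")
        for u, v in g.edges():
            if labels is not None:
                u, v = labels[u], labels[v]
            fh.write(f"{u} {v}\n")


def read_graphml(path: str | os.PathLike) -> tuple[Graph, list]:
    import networkx as nx

    gx = nx.read_graphml(path)
    if gx.is_directed() or gx.is_multigraph():
        gx = nx.Graph(gx)
    return Graph.from_networkx(gx)


def write_graphml(
    g: Graph, path: str | os.PathLike, labels: list | None = None
) -> None:
    import networkx as nx

    gx = g.to_networkx()
    if labels is not None:
        gx = nx.relabel_nodes(gx, {i: lab for i, lab in enumerate(labels)})
    nx.write_graphml(gx, path)
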