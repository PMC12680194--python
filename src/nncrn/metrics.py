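"""Structural metrics: k-cores, efficiency, diameter, Molloy–Reed threshold.

The k-core profile (size of the maximal subgraph with all internal
degrees ≥ k, for every k) diagnoses the dense core that governs where
the giant component emerges near criticality.  Efficiency E is the mean
inverse shortest-path length over node pairs that are connected — pairs
in different components are excluded from the average, not counted as
zero (a flag restores the all-pairs convention).  The Molloy–Reed
criterion p_c = ⟨k⟩/(⟨k²⟩−⟨k⟩) gives the random-failure percolation
threshold of an uncorrelated network with the given degree distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .graph import Graph
from .percolation import MODES

__all__ = [
    "KCoreProfile",
    "EfficiencySummary",
    "k_core_profile",
    "efficiency",
    "efficiency_under_removal",
    "molloy_reed_threshold",
]


@dataclass(frozen=True)
class KCoreProfile:
    """Number of nodes in the k-core for each k ≥ 1 (nonincreasing)."""

    sizes: np.ndarray  # sizes[k-1] = |k-core|

    @property
    def max_core(self) -> int:
        return len(self.sizes)

    def size(self, k: int) -> int:
        if k < 1:
            raise ValueError("k must be >= 1")
        return int(self.sizes[k - 1]) if k <= len(self.sizes) else 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(1, len(self.sizes) + 1), "core_size": self.sizes}
        )


def k_core_profile(g: Graph) -> KCoreProfile:
    """Sizes of all k-cores via iterative pruning (networkx core numbers)."""
    import networkx as nx

    core = nx.core_number(g.to_networkx())
    if not core:
        return KCoreProfile(np.zeros(0, dtype=np.int64))
    values = np.fromiter(core.values(), dtype=np.int64, count=len(core))
    kmax = int(values.max())
    sizes = np.array([(values >= k).sum() for k in range(1, kmax + 1)], dtype=np.int64)
    return KCoreProfile(sizes)


@dataclass(frozen=True)
class EfficiencySummary:
    efficiency: float
    n_pairs: int  # connected ordered pairs entering the average
    diameter: int  # largest finite shortest-path distance scanned


def efficiency(
    g: Graph,
    sample_sources: int | None = None,
    rng: np.random.Generator | None = None,
    all_pairs: bool = False,
) -> EfficiencySummary:
    """Mean inverse shortest-path length over connected ordered pairs.

    With ``sample_sources`` the average runs over BFS trees from that many
    uniformly chosen sources (an unbiased estimator of the full average);
    otherwise every node is a source.  ``all_pairs=True`` switches to the
    global-efficiency convention in which disconnected pairs contribute 0
    and the denominator is N(N−1).
    """
    if g.n_edges == 0:
        raise ValueError("efficiency undefined: graph has no edges")
    indptr, adj = g.to_arrays()
    if sample_sources is None or sample_sources >= g.n_nodes:
        sources = np.arange(g.n_nodes, dtype=np.int64)
    else:
        if rng is None:
            rng = np.random.default_rng()
        sources = rng.choice(g.n_nodes, size=sample_sources, replace=False).astype(
            np.int64
        )
    total, pairs, dmax = K.bfs_efficiency(indptr, adj, sources)
    if pairs == 0:
        raise ValueError("efficiency undefined: no connected pairs")
    if all_pairs:
        denom = len(sources) * (g.n_nodes - 1)
        return EfficiencySummary(float(total) / denom, int(pairs), int(dmax))
    return EfficiencySummary(float(total) / int(pairs), int(pairs), int(dmax))


def _surviving_subgraph(
    g: Graph, mode: str, p: float, rng: np.random.Generator
) -> tuple[Graph, int]:
    """Retain a fraction ``p`` of edges/nodes, matching the removal modes.

    Returns the surviving graph (relabeled to the surviving nodes in node
    modes) and the surviving node count.
    """
    if mode == "random_edge":
        keep = int(round(p * g.n_edges))
        idx = rng.permutation(g.n_edges)[:keep]
        sub = Graph(g.n_nodes)
        for i in idx:
            sub.add_edge(*g.edge_at(int(i)))
        return sub, g.n_nodes
    keep = int(round(p * g.n_nodes))
    if mode == "random_node":
        kept = rng.permutation(g.n_nodes)[:keep]
    elif mode == "targeted_degree":
        deg = g.degrees()
        order = rng.permutation(g.n_nodes)
        order = order[np.argsort(deg[order], kind="stable")]  # ascending degree
        kept = order[:keep]  # survivors = lowest-degree nodes
    else:
        raise ValueError(f"unknown removal mode {mode!r}")
    kept_set = {int(v) for v in kept}
    relabel = {v: i for i, v in enumerate(sorted(kept_set))}
    sub = Graph(len(kept_set))
    for u, v in g.edges():
        if u in kept_set and v in kept_set:
            sub.add_edge(relabel[u], relabel[v])
    return sub, len(kept_set)


def efficiency_under_removal(
    g: Graph,
    mode: str,
    p_grid,
    n_runs: int = 10,
    rng: np.random.Generator | None = None,
    sample_sources: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo E(p): mean efficiency of the surviving graph at each
    retention fraction p (among surviving nodes, connected pairs only).

    Rows where no run leaves a connected pair report NaN.  ``p`` is the
    retained fraction throughout this package.
    """
    if mode not in MODES:
        raise ValueError(f"unknown removal mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for p in p_grid:
        if not (0.0 <= p <= 1.0):
            raise ValueError("retention fractions must lie in [0, 1]")
        vals = []
        for _ in range(n_runs):
            sub, _n = _surviving_subgraph(g, mode, float(p), rng)
            try:
                vals.append(
                    efficiency(sub, sample_sources=sample_sources, rng=rng).efficiency
                )
            except ValueError:
                pass  # no connected pair survived this run
        rows.append(
            {
                "p": float(p),
                "efficiency": float(np.mean(vals)) if vals else np.nan,
                "n_effective_runs": len(vals),
            }
        )
    return pd.DataFrame(rows)


def molloy_reed_threshold(degrees=None, pmf=None) -> float:
    """Percolation threshold p_c = ⟨k⟩/(⟨k²⟩ − ⟨k⟩) of an uncorrelated
    network, from sample moments of a degree sequence or analytic moments
    of a distribution ``pmf = (k, P(k))``."""
    if (degrees is None) == (pmf is None):
        raise ValueError("pass exactly one of a degree sequence or a pmf")
    if degrees is not None:
        d = np.asarray(degrees, dtype=float)
        k1 = d.mean()
        k2 = (d * d).mean()
    else:
        k, p = pmf
        k = np.asarray(k, dtype=float)
        p = np.asarray(p, dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("pmf must sum to 1")
        k1 = float((k * p).sum())
        k2 = float((k * k * p).sum())
    if k2 <= k1:
        raise ValueError("Molloy-Reed criterion undefined: <k^2> <= <k>")
    return k1 / (k2 - k1)
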