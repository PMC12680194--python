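"""Degree–degree correlations at exact shortest-path distance l.

The central observable is the Pearson correlation r_l of the degrees
(k_i, k_j) over all ordered node pairs (i, j) with dist(i, j) = l.  For
l = 1 this is the classical degree assortativity; for l > 1 it measures
long-range degree correlation.  Each unordered pair at distance l
contributes exactly once (twice as ordered pairs), regardless of how many
distinct shortest paths connect it — this is a pair statistic, not a walk
statistic.

Sufficient statistics (pair count and the degree sums S1 = Σk_i,
S2 = Σk_i², S11 = Σk_i·k_j over ordered pairs) are kept in
:class:`PairMomentStats` so that the rewiring chains can update r_l
incrementally.  The sums are held as exact integers: incremental updates
therefore cannot drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .graph import Graph, distance_pairs

__all__ = [
    "NoPairsError",
    "ZeroVarianceError",
    "PairMomentStats",
    "CorrelationProfile",
    "conditional_degree_profile",
    "pearson_r_at_distance",
    "delta_r_for_swap",
]


class NoPairsError(ValueError):
    """No node pairs exist at the requested distance."""


class ZeroVarianceError(ValueError):
    """The degrees over distance-l pairs are all identical, so r_l is undefined."""


@dataclass(frozen=True)
class PairMomentStats:
    """Exact sufficient statistics of the degree pairs at distance ``l``.

    ``n`` counts ordered pairs (``n = 2 M(l)``); the sums run over ordered
    pairs so they are invariant under exchanging pair order.
    """

    l: int
    n: int
    s1: int
    s2: int
    s11: int

    @classmethod
    def from_graph(cls, g: Graph, l: int) -> "PairMomentStats":
        deg = g.degrees()
        pairs, _ = distance_pairs(g, l)
        n = s1 = s2 = s11 = 0
        for i, j in pairs:
            ki = int(deg[i])
            kj = int(deg[j])
            n += 2
            s1 += ki + kj
            s2 += ki * ki + kj * kj
            s11 += 2 * ki * kj
        return cls(l=l, n=n, s1=s1, s2=s2, s11=s11)

    @property
    def m_l(self) -> int:
        """M(l), the number of unordered pairs at distance l."""
        return self.n // 2

    @property
    def r(self) -> float:
        """Pearson's r_l reconstructed from the sufficient statistics."""
        if self.n == 0:
            raise NoPairsError(f"no pairs at distance {self.l}")
        n = float(self.n)
        mu = self.s1 / n
        var = self.s2 / n - mu * mu
        if var <= 1e-12 * max(1.0, self.s2 / n):
            raise ZeroVarianceError(
                f"r_l undefined: zero degree variance at distance {self.l}"
            )
        return (self.s11 / n - mu * mu) / var


@dataclass(frozen=True)
class CorrelationProfile:
    """Joint degree distribution P(k, k'|l) over ordered pairs at distance l.

    ``matrix[a, b]`` is the probability that an ordered pair drawn
    uniformly among pairs at distance ``l`` has degrees
    ``(degrees[a], degrees[b])``; it is symmetric and sums to 1.
    ``counts`` holds the underlying integer ordered-pair counts.
    """

    l: int
    degrees: np.ndarray
    matrix: np.ndarray
    counts: np.ndarray

    @property
    def marginal(self) -> np.ndarray:
        """Degree distribution of one endpoint of a distance-l pair."""
        return self.matrix.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.degrees, columns=self.degrees)

    def to_csv(self, path) -> None:
        """Dense CSV matrix with degree labels on both axes."""
        self.to_dataframe().to_csv(path, index_label="k")


def conditional_degree_profile(g: Graph, l: int) -> CorrelationProfile:
    """P(k, k'|l): the joint degree distribution of pairs at distance l."""
    deg = g.degrees()
    pairs, m_l = distance_pairs(g, l)
    if m_l == 0:
        raise NoPairsError(f"no pairs at distance {l}")
    kvals = np.unique([int(deg[i]) for pair in pairs for i in pair])
    index = {int(k): a for a, k in enumerate(kvals)}
    counts = np.zeros((len(kvals), len(kvals)), dtype=np.int64)
    for i, j in pairs:
        a, b = index[int(deg[i])], index[int(deg[j])]
        counts[a, b] += 1
        counts[b, a] += 1
    return CorrelationProfile(
        l=l, degrees=kvals, matrix=counts / (2.0 * m_l), counts=counts
    )


def pearson_r_at_distance(g: Graph, l: int) -> float:
    """r_l: Pearson correlation of degrees over pairs at exact distance l.

    For ``l = 1`` this equals the standard assortativity coefficient.
    Raises :class:`NoPairsError` when no pairs exist at distance ``l`` and
    :class:`ZeroVarianceError` when all pair degrees are identical (e.g.
    regular graphs).
    """
    return PairMomentStats.from_graph(g, l).r


# -- incremental update under a double-edge swap ---------------------------


def _dist2_partners(g: Graph, a: int) -> set[int]:
    """Nodes at distance exactly 2 from ``a``: non-neighbors sharing at
    least one common neighbor (counted once regardless of multiplicity)."""
    nbrs = g.neighbors(a)
    out: set[int] = set()
    for w in nbrs:
        out.update(g.neighbors(w))
    out.difference_update(nbrs)
    out.discard(a)
    return out


def _affected_pair_contribution(
    g: Graph, endpoints: tuple[int, int, int, int], deg: np.ndarray
) -> tuple[int, int, int, int, int]:
    """Sufficient-statistic contribution of every distance-2 pair touching
    one of the four swap endpoints, in the graph's current state.

    Only pairs with an endpoint in the swap quartet can change distance-2
    status under the swap (the four rewired edges all join quartet
    members, so adjacency — and hence common-neighbor sets — of outside
    pairs is untouched).  Pairs internal to the quartet are counted once.
    """
    eset = set(endpoints)
    n = s1 = s2 = s11 = 0
    for a in endpoints:
        ka = int(deg[a])
        for y in _dist2_partners(g, a):
            if y in eset and y < a:
                continue  # already counted from the smaller endpoint
            ky = int(deg[y])
            n += 2
            s1 += ka + ky
            s2 += ka * ka + ky * ky
            s11 += 2 * ka * ky
    return n, s1, s2, s11


def delta_r_for_swap(
    g: Graph,
    stats: PairMomentStats,
    e1: tuple[int, int],
    e2: tuple[int, int],
) -> tuple[float, PairMomentStats]:
    """r_l after the swap ``(u1,u2),(v1,v2) -> (u1,v2),(v1,u2)``, plus the
    updated sufficient statistics, without leaving the graph modified.

    For ``l = 1`` only the product sum S11 changes (degrees are preserved,
    and the swap exchanges partners within the same four nodes).  For
    ``l = 2`` the distance-2 pair set is re-examined locally around the
    four endpoints, before and after the swap; pairs at distance 1 are
    excluded and common-neighbor multiplicity counts once.

    Raises ``ValueError`` if the swap is inadmissible.
    """
    reason = g.classify_swap(e1, e2)
    if reason is not None:
        raise ValueError(f"inadmissible swap: {reason}")
    u1, u2 = e1
    v1, v2 = e2
    deg = g.degrees()
    if stats.l == 1:
        k = deg
        ds11 = 2 * (
            int(k[u1]) * int(k[v2])
            + int(k[v1]) * int(k[u2])
            - int(k[u1]) * int(k[u2])
            - int(k[v1]) * int(k[v2])
        )
        new = replace(stats, s11=stats.s11 + ds11)
        return new.r, new
    if stats.l != 2:
        raise NotImplementedError("incremental update implemented for l in {1, 2}")
    quartet = (u1, u2, v1, v2)
    before = _affected_pair_contribution(g, quartet, deg)
    out = g.swap_edges(e1, e2)
    assert out.applied
    try:
        after = _affected_pair_contribution(g, quartet, deg)
    finally:
        back = g.swap_edges((u1, v2), (v1, u2))  # exact inverse swap
        assert back.applied
    new = PairMomentStats(
        l=2,
        n=stats.n - before[0] + after[0],
        s1=stats.s1 - before[1] + after[1],
        s2=stats.s2 - before[2] + after[2],
        s11=stats.s11 - before[3] + after[3],
    )
    return new.r, new
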