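"""Initial network generators.

Two random families feed the rewiring chains: Erdős–Rényi graphs with a
fixed edge count (so the mean degree ⟨k⟩ is controlled exactly) and
configuration-model graphs with a truncated power-law degree distribution
P(k) ∝ k^(−γ) on k ∈ [k_min, k_c], with the structural cutoff
k_c = ⌊√N⌋ by default so that the simple-graph constraint does not induce
degree correlations by itself.  Deterministic toy fixtures (paths, stars,
cycles, cliques) round out the family for tests and examples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .graph import Graph

__all__ = [
    "GeneratorSpec",
    "erdos_renyi",
    "powerlaw_configuration",
    "fixture_graph",
    "generate",
    "truncated_powerlaw_pmf",
]


def truncated_powerlaw_pmf(
    gamma: float, k_min: int, k_cutoff: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized P(k) = c·k^(−γ) on the integer support [k_min, k_cutoff]."""
    if gamma <= 1:
        raise ValueError("power-law exponent must exceed 1")
    if not (1 <= k_min <= k_cutoff):
        raise ValueError("need 1 <= k_min <= k_cutoff")
    k = np.arange(k_min, k_cutoff + 1, dtype=np.int64)
    w = k.astype(float) ** (-gamma)
    return k, w / w.sum()


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of an initial-network family.

    ``family`` is one of ``erdos_renyi``, ``powerlaw_configuration`` or
    ``fixture``.  For power-law graphs the cutoff defaults to the
    structural cutoff ⌊√N⌋ when left unset.
    """

    family: str
    n: int = 0
    mean_degree: float | None = None
    gamma: float | None = None
    k_min: int | None = None
    k_cutoff: int | None = None
    fixture_name: str | None = None
    seed: int | None = None

    @classmethod
    def er(cls, n: int, mean_degree: float, seed: int | None = None):
        return cls(family="erdos_renyi", n=n, mean_degree=mean_degree, seed=seed)

    @classmethod
    def powerlaw(
        cls,
        n: int,
        gamma: float = 2.5,
        k_min: int = 2,
        k_cutoff: int | None = None,
        seed: int | None = None,
    ):
        return cls(
            family="powerlaw_configuration",
            n=n,
            gamma=gamma,
            k_min=k_min,
            k_cutoff=k_cutoff,
            seed=seed,
        )

    def resolved_cutoff(self) -> int:
        kc = self.k_cutoff if self.k_cutoff is not None else int(np.floor(np.sqrt(self.n)))
        return min(kc, self.n - 1)

    def pmf(self) -> tuple[np.ndarray, np.ndarray]:
        if self.family != "powerlaw_configuration":
            raise ValueError("pmf defined for power-law specs only")
        return truncated_powerlaw_pmf(self.gamma, self.k_min, self.resolved_cutoff())


def _rng(spec_seed, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(spec_seed)


def erdos_renyi(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> Graph:
    """G(N, M) with M = round(N⟨k⟩/2) distinct uniformly chosen edges.

    Fixing the edge count (rather than an independent edge probability)
    pins the mean degree exactly, which is the quantity the rewiring
    stage conditions on.
    """
    n = spec.n
    if n < 2:
        raise ValueError("need at least 2 nodes")
    m = int(round(n * spec.mean_degree / 2.0))
    if m > n * (n - 1) // 2:
        raise ValueError(f"target edge count {m} infeasible for {n} nodes")
    rng = _rng(spec.seed, rng)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < m:
        k = m - len(chosen)
        us = rng.integers(0, n, size=2 * k + 8)
        vs = rng.integers(0, n, size=2 * k + 8)
        for u, v in zip(us, vs):
            if u == v:
                continue
            e = (int(u), int(v)) if u < v else (int(v), int(u))
            if e not in chosen:
                chosen.add(e)
                if len(chosen) == m:
                    break
    g = Graph(n)
    for u, v in sorted(chosen):
        g.add_edge(u, v)
    return g


def _draw_degree_sequence(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    k, p = spec.pmf()
    cdf = np.cumsum(p)
    deg = k[np.searchsorted(cdf, rng.random(spec.n), side="right").clip(0, len(k) - 1)]
    # parity fix: redraw one uniformly chosen node's degree until the sum is even
    while int(deg.sum()) % 2 == 1:
        i = int(rng.integers(spec.n))
        deg[i] = k[min(np.searchsorted(cdf, rng.random(), side="right"), len(k) - 1)]
    return deg.astype(np.int64)


def powerlaw_configuration(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> Graph:
    """Configuration model with a truncated power-law degree sequence.

    Degrees are an i.i.d. inverse-CDF sample from the truncated
    distribution (with a parity fix).  Uniform stub matching is followed
    by a simplicity repair that removes self-loops and parallel edges via
    degree-preserving double-edge swaps against uniformly chosen edges,
    so the realized degree sequence equals the drawn one exactly.
    """
    rng = _rng(spec.seed, rng)
    deg = _draw_degree_sequence(spec, rng)
    stubs = np.repeat(np.arange(spec.n, dtype=np.int64), deg)
    rng.shuffle(stubs)
    edges = [
        (int(a), int(b)) if a < b else (int(b), int(a))
        for a, b in zip(stubs[0::2], stubs[1::2])
    ]
    edges = _repair_to_simple(edges, rng)
    g = Graph(spec.n)
    for u, v in edges:
        g.add_edge(u, v)
    if not np.array_equal(g.degrees(), deg):  # pragma: no cover - safety net
        raise AssertionError("simplicity repair altered the degree sequence")
    return g


def _repair_to_simple(
    edges: list[tuple[int, int]], rng: np.random.Generator, max_rounds: int = 10_000_000
) -> list[tuple[int, int]]:
    """Remove loops/parallel edges by double-edge swaps; degrees unchanged."""
    from collections import Counter

    count = Counter(edges)

    def is_bad(e):
        return e[0] == e[1] or count[e] > 1

    bad = {i for i, e in enumerate(edges) if is_bad(e)}
    m = len(edges)
    attempts = 0
    while bad:
        attempts += 1
        if attempts > max_rounds:
            raise RuntimeError("simplicity repair failed to converge")
        i = next(iter(bad))
        if not is_bad(edges[i]):  # a parallel partner may have moved away
            bad.discard(i)
            continue
        a, b = edges[i]
        if rng.integers(2):
            a, b = b, a
        j = int(rng.integers(m))
        if j == i:
            continue
        c, d = edges[j]
        if rng.integers(2):
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 == e2 or count[e1] > 0 or count[e2] > 0:
            continue
        for old in (edges[i], edges[j]):
            count[old] -= 1
            if count[old] == 0:
                del count[old]
        edges[i] = e1
        edges[j] = e2
        count[e1] += 1
        count[e2] += 1
        for idx in (i, j):
            if is_bad(edges[idx]):
                bad.add(idx)
            else:
                bad.discard(idx)
    return edges


_FIXTURE_RE = re.compile(r"^(path|star|cycle|clique)_(\d+)$")


def fixture_graph(name: str) -> Graph:
    """Deterministic toy graphs: ``path_n``, ``star_n`` (one center,
    n−1 leaves), ``cycle_n``, ``clique_n``."""
    m = _FIXTURE_RE.match(name)
    if not m:
        raise ValueError(f"unknown fixture {name!r}")
    kind, n = m.group(1), int(m.group(2))
    if n < 1 or (kind == "cycle" and n < 3):
        raise ValueError(f"fixture {name!r} too small")
    g = Graph(n)
    if kind == "path":
        for i in range(n - 1):
            g.add_edge(i, i + 1)
    elif kind == "star":
        for i in range(1, n):
            g.add_edge(0, i)
    elif kind == "cycle":
        for i in range(n):
            g.add_edge(i, (i + 1) % n)
    elif kind == "clique":
        for i in range(n):
            for j in range(i + 1, n):
                g.add_edge(i, j)
    return g


def generate(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> Graph:
    """Dispatch on ``spec.family``."""
    if spec.family == "erdos_renyi":
        return erdos_renyi(spec, rng)
    if spec.family == "powerlaw_configuration":
        return powerlaw_configuration(spec, rng)
    if spec.family == "fixture":
        return fixture_graph(spec.fixture_name)
    raise ValueError(f"unknown generator family {spec.family!r}")
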