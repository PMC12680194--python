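"""Metropolis–Hastings edge rewiring with controlled degree correlations.

Two chains over double-edge swaps:

* distance-1 chain — both edges drawn uniformly; the degree sequence is a
  hard constraint and the coupling J biases the assortativity r1, so the
  equilibrium ensemble is the exponential family Π(G) ∝ exp(J·r1(G)) over
  graphs with the given degree sequence (a 1-NNCRN when J sweeps r1).
* distance-2 chain — the second edge is drawn with its source degree
  matched to the first edge's source, which additionally preserves the
  joint degree profile P(k,k'|l=1) (hence r1) exactly, while J biases the
  second-neighbor correlation r2: Π(G) ∝ exp(J·r2(G)).

Sign convention: positive J drives the targeted correlation positive
(acceptance min(1, exp(+J·Δr))).  Set ``paper_sign=True`` for the
opposite convention min(1, exp(−J·Δr)), under which positive J favors
negative r.

Every proposal — including lazy steps (probability 1/2 by default, kept
for aperiodicity) and structurally rejected swaps — consumes one step of
the budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .correlation import (
    PairMomentStats,
    ZeroVarianceError,
    delta_r_for_swap,
)
from .graph import DegreeEdgeBuckets, Graph

__all__ = [
    "RewiringConfig",
    "RewiringTrace",
    "acceptance_probability",
    "mh_step",
    "generate_1nncrn",
    "generate_2nncrn",
    "estimate_r2ext",
]

_OUTCOMES = ("applied", "rejected-lazy", "rejected-structural", "rejected-metropolis")


@dataclass(frozen=True)
class RewiringConfig:
    """Parameters of one rewiring chain.

    ``J`` is the coupling; with ``j_units="M"`` it is interpreted in units
    of the edge count M (the convention used for the study grids, where
    effective couplings must scale with M).  The proposal budget is
    ``n_proposals`` when given, else ``budget_sweeps·M`` (default 10⁴
    sweeps, a conservative equilibration budget).
    """

    target_distance: int
    J: float = 0.0
    j_units: str = "absolute"  # "absolute" | "M"
    n_proposals: int | None = None
    budget_sweeps: float = 1e4
    lazy_prob: float = 0.5
    seed: int | None = None
    full_recompute_interval: int = 100_000
    trace_points: int = 200
    paper_sign: bool = False

    def __post_init__(self):
        if self.target_distance not in (1, 2):
            raise ValueError("target distance must be 1 or 2")
        if not (0.0 <= self.lazy_prob <= 1.0):
            raise ValueError("lazy probability must lie in [0, 1]")
        if self.n_proposals is not None and self.n_proposals < 0:
            raise ValueError("proposal budget must be nonnegative")
        if self.j_units not in ("absolute", "M"):
            raise ValueError("j_units must be 'absolute' or 'M'")

    def effective_J(self, n_edges: int) -> float:
        """Coupling as used in the acceptance rule (sign resolved)."""
        j = self.J * n_edges if self.j_units == "M" else self.J
        return -j if self.paper_sign else j

    def budget(self, n_edges: int) -> int:
        if self.n_proposals is not None:
            return self.n_proposals
        return int(round(self.budget_sweeps * n_edges))


@dataclass
class RewiringTrace:
    """Thinned chain diagnostics: r time series, outcome tallies, finals."""

    target_distance: int
    n_proposals: int
    trace_every: int
    outcome_counts: dict[str, int]
    r1_series: np.ndarray | None
    r2_series: np.ndarray | None
    outcome_series: np.ndarray | None
    final_r1: float | None
    final_r2: float | None

    @property
    def acceptance_rate(self) -> float:
        return self.outcome_counts["applied"] / max(1, self.n_proposals)

    def to_dataframe(self) -> pd.DataFrame:
        """Fixed-layout table: proposal_index, r1, r2, outcome."""
        npts = 0
        for s in (self.r1_series, self.r2_series):
            if s is not None:
                npts = len(s)
        idx = (np.arange(npts) + 1) * self.trace_every
        r1 = self.r1_series if self.r1_series is not None else np.full(npts, np.nan)
        r2 = self.r2_series if self.r2_series is not None else np.full(npts, np.nan)
        out = (
            [_OUTCOMES[int(o)] for o in self.outcome_series]
            if self.outcome_series is not None
            else [""] * npts
        )
        return pd.DataFrame(
            {"proposal_index": idx, "r1": r1, "r2": r2, "outcome": out}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def acceptance_probability(J: float, delta_r: float, paper_sign: bool = False) -> float:
    """min(1, exp(J·Δr)) — or min(1, exp(−J·Δr)) under ``paper_sign``."""
    j = -J if paper_sign else J
    return min(1.0, math.exp(j * delta_r))


def _r_or_zero(stats: PairMomentStats) -> float:
    try:
        return stats.r
    except ValueError:
        return 0.0


def mh_step(
    g: Graph,
    stats: PairMomentStats,
    cfg: RewiringConfig,
    rng: np.random.Generator,
    buckets: DegreeEdgeBuckets | None = None,
) -> tuple[str, PairMomentStats]:
    """One chain step on ``g`` in place (reference implementation).

    Returns ``(outcome, stats)`` where stats reflects the (possibly
    unchanged) post-step state.  ``buckets`` may be passed to amortize the
    degree index for the distance-2 chain.
    """
    if stats.l != cfg.target_distance:
        raise ValueError("stats distance does not match the chain target")
    if rng.random() < cfg.lazy_prob:
        return "rejected-lazy", stats
    e1 = g.sample_ordered_edge(rng)
    if cfg.target_distance == 1:
        e2 = g.sample_ordered_edge(rng)
    else:
        if buckets is None:
            buckets = DegreeEdgeBuckets(g)
        e2 = buckets.sample(g.degree(e1[0]), rng)
    if g.classify_swap(e1, e2) is not None:
        return "rejected-structural", stats
    r_prev = _r_or_zero(stats)
    r_next, new_stats = delta_r_for_swap(g, stats, e1, e2)
    jeff = cfg.effective_J(g.n_edges)
    dr = r_next - r_prev
    if jeff * dr >= 0.0 or rng.random() < math.exp(jeff * dr):
        out = g.swap_edges(e1, e2)
        assert out.applied
        return "applied", new_stats
    return "rejected-metropolis", stats


def _kernel_seed(cfg: RewiringConfig, rng: np.random.Generator | None) -> int:
    if rng is not None:
        return int(rng.integers(2**31))
    return int(np.random.default_rng(cfg.seed).integers(2**31))


def _check_degree_variance(deg: np.ndarray) -> None:
    if np.all(deg == deg[0]):
        raise ZeroVarianceError(
            "r_l undefined: the graph is regular, the chain target is degenerate"
        )


def generate_1nncrn(
    g0: Graph,
    cfg: RewiringConfig,
    rng: np.random.Generator | None = None,
    record_r2: bool = False,
) -> tuple[Graph, RewiringTrace]:
    """Run the distance-1 chain on a copy of ``g0``.

    The output has exactly the degree sequence of ``g0``; r1 equilibrates
    around a value set by J.  ``record_r2`` adds a (more expensive) r2
    series to the trace.
    """
    if cfg.target_distance != 1:
        raise ValueError("config targets distance != 1")
    deg = g0.degrees()
    _check_degree_variance(deg)
    indptr, adj = g0.to_arrays()
    n_steps = cfg.budget(g0.n_edges)
    trace_every = max(1, n_steps // cfg.trace_points) if cfg.trace_points else 0
    r1, counts, tr1, tr2, tro = K.rewire_l1(
        indptr,
        adj,
        deg,
        cfg.effective_J(g0.n_edges),
        n_steps,
        cfg.lazy_prob,
        _kernel_seed(cfg, rng),
        trace_every,
        record_r2,
    )
    g = Graph.from_arrays(indptr, adj)
    mark = np.zeros(g.n_nodes, np.int64)
    c2, a2, b2, p2, _ = K.full_d2_stats(indptr, adj, deg, mark, 0)
    trace = RewiringTrace(
        target_distance=1,
        n_proposals=n_steps,
        trace_every=trace_every,
        outcome_counts=dict(zip(_OUTCOMES, (int(c) for c in counts))),
        r1_series=tr1,
        r2_series=tr2 if record_r2 else None,
        outcome_series=tro,
        final_r1=float(r1),
        final_r2=float(K._r_of(c2, a2, b2, p2)),
    )
    return g, trace


def _degree_index(deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dmax = int(deg.max())
    counts = np.bincount(deg, minlength=dmax + 1)
    indptr = np.zeros(dmax + 2, np.int64)
    np.cumsum(counts, out=indptr[1:])
    data = np.argsort(deg, kind="stable").astype(np.int64)
    return indptr, data


def generate_2nncrn(
    g1: Graph,
    cfg: RewiringConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Graph, RewiringTrace]:
    """Run the distance-2 chain on a copy of ``g1``.

    The degree sequence and the joint degree profile at distance 1 are
    hard constraints (exact integer preservation); r2 equilibrates around
    a value set by J.
    """
    if cfg.target_distance != 2:
        raise ValueError("config targets distance != 2")
    deg = g1.degrees()
    _check_degree_variance(deg)
    indptr, adj = g1.to_arrays()
    nbd_indptr, nbd_data = _degree_index(deg)
    n_steps = cfg.budget(g1.n_edges)
    trace_every = max(1, n_steps // cfg.trace_points) if cfg.trace_points else 0
    status, cnt, s1, s2, s11, counts, tr2, tro = K.rewire_l2(
        indptr,
        adj,
        deg,
        nbd_indptr,
        nbd_data,
        cfg.effective_J(g1.n_edges),
        n_steps,
        cfg.lazy_prob,
        _kernel_seed(cfg, rng),
        trace_every,
        cfg.full_recompute_interval,
    )
    if status != 0:
        raise RuntimeError(
            "corrupted chain state: periodic full recomputation disagreed "
            "with the incrementally maintained distance-2 statistics"
        )
    g = Graph.from_arrays(indptr, adj)
    trace = RewiringTrace(
        target_distance=2,
        n_proposals=n_steps,
        trace_every=trace_every,
        outcome_counts=dict(zip(_OUTCOMES, (int(c) for c in counts))),
        r1_series=None,
        r2_series=tr2,
        outcome_series=tro,
        final_r1=_r_or_zero(PairMomentStats.from_graph(g, 1)),
        final_r2=float(K._r_of(cnt, s1, s2, s11)),
    )
    return g, trace


def estimate_r2ext(
    g1: Graph,
    n_samples: int,
    cfg: RewiringConfig,
    rng: np.random.Generator | None = None,
    burn_in_fraction: float = 0.5,
) -> tuple[float, float | None]:
    """Extrinsic second-neighbor correlation baseline r2_ext of ``g1``.

    Runs the distance-2 chain at J = 0 (so the ensemble is uniform over
    graphs sharing the degree sequence and distance-1 profile of ``g1``)
    and averages r2 over ``n_samples`` spaced samples taken after a
    burn-in.  Returns ``(mean, sd)``; sd is None for a single sample.
    """
    if cfg.target_distance != 2 or cfg.J != 0.0:
        raise ValueError("r2_ext is defined by the distance-2 chain at J = 0")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    n_steps = cfg.budget(g1.n_edges)
    burn = int(burn_in_fraction * n_steps)
    every = max(1, (n_steps - burn) // n_samples)
    # thin the whole chain at the sampling interval, keep the tail
    points = max(1, n_steps // every)
    cfg2 = RewiringConfig(
        target_distance=2,
        J=0.0,
        n_proposals=n_steps,
        lazy_prob=cfg.lazy_prob,
        seed=cfg.seed,
        full_recompute_interval=cfg.full_recompute_interval,
        trace_points=points,
        paper_sign=cfg.paper_sign,
    )
    _, trace = generate_2nncrn(g1, cfg2, rng)
    samples = np.asarray(trace.r2_series)[-n_samples:]
    mean = float(np.mean(samples))
    sd = float(np.std(samples, ddof=1)) if len(samples) > 1 else None
    return mean, sd
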