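"""Percolation-based structural robustness.

Networks are dismantled by random edge failure, random node failure, or a
degree-based targeted attack (nodes removed in decreasing order of their
initial degree).  The Newman–Ziff construction runs the process in
reverse — elements are *added* in the reverse of the removal order under
incremental union-find — giving the largest-component size at every
occupation number n in near-linear time.

All curves and summary measures live on the microcanonical grid (exact
occupation number n, with p = n/M or n/N); they agree with the canonical
fixed-probability ensemble to O(1/√M) at the sizes studied here.
Summary measures:

* f_x%  — 1 − p_x%, where p_x% = sup{p : ⟨N_LCC(p)⟩ < x·N} (default
  x = 1%): the removed fraction the network tolerates before the giant
  component collapses below x·N.
* R     — the area under S(p) = ⟨N_LCC(p)⟩/N over the grid (Schneider's
  robustness): average connectivity over the whole removal process.
* susceptibility χ(p) = (⟨N_LCC²⟩ − ⟨N_LCC⟩²)/⟨N_LCC⟩, whose local peaks
  locate the (possibly multiple) percolation transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import _kernels as K
from .graph import Graph

__all__ = [
    "RemovalPlan",
    "PercolationCurve",
    "Peak",
    "RobustnessSummary",
    "make_removal_plan",
    "newman_ziff_run",
    "ensemble_curves",
    "f_threshold",
    "robustness_R",
    "susceptibility_peaks",
    "summarize_robustness",
]

MODES = ("random_edge", "random_node", "targeted_degree")


@dataclass(frozen=True)
class RemovalPlan:
    """A full removal order, stored in ADDITION order (reverse of removal).

    ``elements`` holds edges as an (M, 2) endpoint array for edge mode,
    or node ids (length N) for the node modes.
    """

    mode: str
    elements: np.ndarray
    n_nodes: int
    n_edges: int


def make_removal_plan(
    g: Graph, mode: str, rng: np.random.Generator
) -> RemovalPlan:
    """Draw one removal order.

    Random modes permute edges/nodes uniformly.  The targeted mode
    removes nodes by decreasing INITIAL degree (static order — required
    for a fixed Newman–Ziff addition sequence), ties broken uniformly at
    random, and therefore stores nodes by nondecreasing degree.
    """
    if mode not in MODES:
        raise ValueError(f"unknown removal mode {mode!r}")
    if mode == "random_edge":
        edges = np.array(g.edges(), dtype=np.int64).reshape(-1, 2)
        rng.shuffle(edges, axis=0)
        return RemovalPlan(mode, edges, g.n_nodes, g.n_edges)
    order = rng.permutation(g.n_nodes).astype(np.int64)
    if mode == "targeted_degree":
        deg = g.degrees()
        order = order[np.argsort(deg[order], kind="stable")]
    return RemovalPlan(mode, order, g.n_nodes, g.n_edges)


def newman_ziff_run(g: Graph, plan: RemovalPlan) -> np.ndarray:
    """Largest-component size after n additions, n = 0..(M or N).

    Edge mode: all nodes are present throughout, so the sequence starts
    at 1 (any single node).  Node modes: only edges between present nodes
    are active and the sequence starts at 0.  The sequence is
    nondecreasing by construction.
    """
    if plan.n_nodes != g.n_nodes or plan.n_edges != g.n_edges:
        raise ValueError("removal plan does not match the graph")
    if plan.mode == "random_edge":
        if plan.elements.shape[0] != g.n_edges:
            raise ValueError("edge plan size mismatch")
        return K.nz_edges(g.n_nodes, plan.elements)
    if plan.elements.shape[0] != g.n_nodes:
        raise ValueError("node plan size mismatch")
    indptr, adj = g.to_arrays()
    return K.nz_nodes(indptr, adj, plan.elements)


@dataclass
class PercolationCurve:
    """Ensemble moments of the largest component on the occupation grid."""

    mode: str
    n_nodes: int
    n_edges: int
    n_runs: int
    occupied: np.ndarray  # grid of occupation numbers n
    mean_lcc: np.ndarray
    second_moment_lcc: np.ndarray

    @property
    def p(self) -> np.ndarray:
        denom = self.n_edges if self.mode == "random_edge" else self.n_nodes
        return self.occupied / max(1, denom)

    @property
    def s(self) -> np.ndarray:
        """S(p) = ⟨N_LCC⟩/N, normalized by the full node count."""
        return self.mean_lcc / self.n_nodes

    @property
    def chi(self) -> np.ndarray:
        """χ = (⟨N_LCC²⟩ − ⟨N_LCC⟩²)/⟨N_LCC⟩; 0 where ⟨N_LCC⟩ = 0."""
        out = np.zeros_like(self.mean_lcc)
        pos = self.mean_lcc > 0
        out[pos] = (
            self.second_moment_lcc[pos] - self.mean_lcc[pos] ** 2
        ) / self.mean_lcc[pos]
        return np.maximum(out, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.occupied,
                "p": self.p,
                "mean_lcc": self.mean_lcc,
                "second_moment_lcc": self.second_moment_lcc,
                "chi": self.chi,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def ensemble_curves(
    g: Graph, mode: str, n_runs: int, rng: np.random.Generator
) -> PercolationCurve:
    """Average Newman–Ziff runs over ``n_runs`` independent removal orders,
    accumulating first and second moments of N_LCC at fixed occupation
    number (microcanonical grid)."""
    if n_runs < 1:
        raise ValueError("need at least one run")
    grid = (g.n_edges if mode == "random_edge" else g.n_nodes) + 1
    acc = np.zeros(grid)
    acc2 = np.zeros(grid)
    for _ in range(n_runs):
        seq = newman_ziff_run(g, make_removal_plan(g, mode, rng)).astype(float)
        acc += seq
        acc2 += seq * seq
    return PercolationCurve(
        mode=mode,
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        n_runs=n_runs,
        occupied=np.arange(grid),
        mean_lcc=acc / n_runs,
        second_moment_lcc=acc2 / n_runs,
    )


def f_threshold(curve: PercolationCurve, x: float = 0.01) -> tuple[float, float]:
    """(p_x%, f_x%): the collapse threshold at relative size ``x``.

    p_x% is the largest grid p at which ⟨N_LCC⟩ < x·N; f_x% = 1 − p_x%.
    When the condition holds nowhere (e.g. x·N ≤ 1 under edge removal,
    where a single node always survives) the convention is p_x% = 0,
    f_x% = 1.
    """
    below = curve.mean_lcc < x * curve.n_nodes
    if not below.any():
        return 0.0, 1.0
    p_x = float(curve.p[np.flatnonzero(below)[-1]])
    return p_x, 1.0 - p_x


def robustness_R(curve: PercolationCurve) -> float:
    """Schneider's R: the uniform average of S over the occupation grid,
    which equals ∫₀¹ E[S(p)] dp exactly under binomial occupancy."""
    return float(curve.s.mean())


@dataclass(frozen=True)
class Peak:
    p_star: float
    chi_star: float

    @property
    def f_star(self) -> float:
        return 1.0 - self.p_star


def susceptibility_peaks(
    curve: PercolationCurve,
    smooth_window: int = 1,
    min_prominence_frac: float = 0.0,
) -> list[Peak]:
    """Local maxima of χ over the grid, sorted by p*.

    ``smooth_window`` > 1 applies a centered moving average before the
    peak search; ``min_prominence_frac`` drops maxima whose prominence is
    below that fraction of the χ maximum (finite ensembles carry shot
    noise on χ, and physically meaningful transitions are the prominent
    maxima).  Grid points with ⟨N_LCC⟩ = 0 carry χ = 0 and cannot be
    peaks.  Requires at least 3 grid points and an ensemble (n_runs ≥ 2,
    otherwise χ is identically zero and no peak is meaningful).
    """
    chi = curve.chi
    if len(chi) < 3:
        raise ValueError("need at least 3 grid points to locate peaks")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        chi = np.convolve(chi, kernel, mode="same")
    prominence = None
    if min_prominence_frac > 0.0 and chi.max() > 0.0:
        prominence = min_prominence_frac * chi.max()
    idx, _ = find_peaks(chi, prominence=prominence)
    return [Peak(float(curve.p[i]), float(chi[i])) for i in idx]


@dataclass
class RobustnessSummary:
    """f_x%, R and the susceptibility peaks of one percolation ensemble."""

    mode: str
    threshold_x: float
    p_x: float
    f_x: float
    R: float
    peaks: list[Peak] = field(default_factory=list)
    n_runs: int = 0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "threshold_x": self.threshold_x,
            "p_x": self.p_x,
            "f_x": self.f_x,
            "R": self.R,
            "peaks": [
                {"p_star": pk.p_star, "chi_star": pk.chi_star, "f_star": pk.f_star}
                for pk in self.peaks
            ],
            "runs": self.n_runs,
        }


def summarize_robustness(
    curve: PercolationCurve, x: float = 0.01, smooth_window: int = 1
) -> RobustnessSummary:
    p_x, f_x = f_threshold(curve, x)
    peaks = susceptibility_peaks(curve, smooth_window) if curve.n_runs >= 2 else []
    return RobustnessSummary(
        mode=curve.mode,
        threshold_x=x,
        p_x=p_x,
        f_x=f_x,
        R=robustness_R(curve),
        peaks=peaks,
        n_runs=curve.n_runs,
    )
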