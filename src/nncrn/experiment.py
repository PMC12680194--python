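"""Config-driven experiment grids over the (J1, J2) coupling plane.

One grid cell is a coupling pair (J1, J2), both in units of the edge
count M.  Per realization the pipeline is: generate an initial network
G0 → distance-1 chain at J1 (sets r1) → distance-2 chain at J2 (sets r2
with r1 and the distance-1 profile held fixed) → percolation robustness
(f_x%, R, susceptibility peaks) per removal mode.  All randomness
derives deterministically from the master seed via seed sequences keyed
by (cell, realization), so a grid is exactly reproducible.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .generators import GeneratorSpec, generate
from .graph import Graph
from .io import write_edgelist
from .percolation import ensemble_curves, summarize_robustness
from .rewiring import RewiringConfig, generate_1nncrn, generate_2nncrn

__all__ = ["ExperimentConfig", "CellSummary", "run_grid", "summarize"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full grid specification; couplings are in units of M."""

    generator: GeneratorSpec
    j1_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    j2_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    n_realizations: int = 100
    rewiring_sweeps: float = 1e4  # proposals per chain, in units of M
    percolation_modes: tuple[str, ...] = ("random_edge",)
    percolation_runs: int = 100
    threshold_x: float = 0.01
    master_seed: int = 0
    archive_networks: bool = False
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        gen = GeneratorSpec(**raw.pop("generator"))
        for key in ("j1_values", "j2_values", "percolation_modes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)


@dataclass
class CellSummary:
    """Per-realization observables and aggregates of one (J1, J2) cell."""

    j1: float
    j2: float
    r1: list[float] = field(default_factory=list)
    r2: list[float] = field(default_factory=list)
    f_x: dict[str, list[float]] = field(default_factory=dict)
    R: dict[str, list[float]] = field(default_factory=dict)
    peak_positions: dict[str, list[list[float]]] = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    @property
    def n_realizations(self) -> int:
        return len(self.r1)

    @staticmethod
    def _agg(values: list[float]) -> dict[str, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return {
            "mean": float(arr.mean()),
            "sd": sd,
            "ci3se": 3.0 * sd / np.sqrt(len(arr)),  # 3x standard error
        }

    def aggregates(self) -> dict:
        out = {"j1": self.j1, "j2": self.j2, "n": self.n_realizations}
        out["r1"] = self._agg(self.r1)
        out["r2"] = self._agg(self.r2)
        for mode in self.f_x:
            out[f"f_x[{mode}]"] = self._agg(self.f_x[mode])
            out[f"R[{mode}]"] = self._agg(self.R[mode])
        return out


def _cell_seed(master: int, j1_idx: int, j2_idx: int, rep: int, stage: int) -> int:
    """Stable per-(cell, realization, stage) seed below 2^31."""
    # indices are offset by 1 so the sentinel -1 ("stage before the grid")
    # maps to 0; SeedSequence entries must be non-negative
    ss = np.random.SeedSequence(
        [int(master), j1_idx + 1, j2_idx + 1, rep, stage]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(cfg: ExperimentConfig, log=None) -> list[CellSummary]:
    """Execute the full grid; returns one CellSummary per (J1, J2).

    Failures inside a single realization are logged and skipped; they do
    not abort the grid.  With ``cfg.outdir`` set, summary tables, per-cell
    JSON and (optionally) the rewired edge lists are written there.
    """
    cells = {
        (j1, j2): CellSummary(j1=j1, j2=j2)
        for j1 in cfg.j1_values
        for j2 in cfg.j2_values
    }
    logf = None
    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        logf = open(os.path.join(cfg.outdir, "log.jsonl"), "w")

    def emit(record: dict) -> None:
        record["time"] = time.time()
        if logf:
            logf.write(json.dumps(record) + "\n")
            logf.flush()
        if log:
            log(record)

    try:
        for rep in range(cfg.n_realizations):
            g0_seed = _cell_seed(cfg.master_seed, -1, -1, rep, 0)
            g0 = generate(cfg.generator, np.random.default_rng(g0_seed))
            for i1, j1 in enumerate(cfg.j1_values):
                s1 = _cell_seed(cfg.master_seed, i1, -1, rep, 1)
                cfg1 = RewiringConfig(
                    target_distance=1,
                    J=j1,
                    j_units="M",
                    budget_sweeps=cfg.rewiring_sweeps,
                    seed=s1,
                )
                g1, _ = generate_1nncrn(g0, cfg1)
                for i2, j2 in enumerate(cfg.j2_values):
                    cell = cells[(j1, j2)]
                    try:
                        s2 = _cell_seed(cfg.master_seed, i1, i2, rep, 2)
                        cfg2 = RewiringConfig(
                            target_distance=2,
                            J=j2,
                            j_units="M",
                            budget_sweeps=cfg.rewiring_sweeps,
                            seed=s2,
                        )
                        g2, trace = generate_2nncrn(g1, cfg2)
                        cell.r1.append(trace.final_r1)
                        cell.r2.append(trace.final_r2)
                        cell.seeds.append(s2)
                        for mode in cfg.percolation_modes:
                            sp = _cell_seed(cfg.master_seed, i1, i2, rep, 3)
                            curve = ensemble_curves(
                                g2,
                                mode,
                                cfg.percolation_runs,
                                np.random.default_rng(sp),
                            )
                            summary = summarize_robustness(curve, cfg.threshold_x)
                            cell.f_x.setdefault(mode, []).append(summary.f_x)
                            cell.R.setdefault(mode, []).append(summary.R)
                            cell.peak_positions.setdefault(mode, []).append(
                                [pk.p_star for pk in summary.peaks]
                            )
                        if cfg.archive_networks and cfg.outdir:
                            name = f"net_j1{j1:+g}_j2{j2:+g}_rep{rep}.edgelist"
                            write_edgelist(g2, os.path.join(cfg.outdir, name))
                        emit(
                            {
                                "event": "cell_done",
                                "j1": j1,
                                "j2": j2,
                                "rep": rep,
                                "seed": s2,
                                "r1": cell.r1[-1],
                                "r2": cell.r2[-1],
                            }
                        )
                    except Exception as exc:  # noqa: BLE001 - logged, not fatal
                        emit(
                            {
                                "event": "cell_failed",
                                "j1": j1,
                                "j2": j2,
                                "rep": rep,
                                "error": repr(exc),
                            }
                        )
    finally:
        if logf:
            logf.close()

    result = list(cells.values())
    if cfg.outdir:
        table = summarize(result)
        table.to_csv(os.path.join(cfg.outdir, "summary.csv"), index=False)
        with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
            json.dump([c.aggregates() for c in result], fh, indent=2)
    return result


def summarize(cells: list[CellSummary]) -> pd.DataFrame:
    """One row per (J1, J2): mean/sd/3·SE of r1, r2 and per-mode f_x, R."""
    if not cells:
        raise ValueError("no cells to summarize")
    rows = []
    for cell in cells:
        agg = cell.aggregates()
        row = {"j1": agg["j1"], "j2": agg["j2"], "n": agg["n"]}
        for key, val in agg.items():
            if isinstance(val, dict):
                for stat, x in val.items():
                    row[f"{key}_{stat}"] = x
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["j1", "j2"]).reset_index(drop=True)
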