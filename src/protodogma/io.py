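"""File formats, run configuration, and synthetic snapshot fixtures.

All artifacts are plain text, chosen for diffability:

- run configuration: YAML (unknown keys rejected, defaults applied);
- snapshots: JSONL, one record per replicator
  ``{step, cell_id, rep_id, rtype, k: [8 floats], state}`` plus one record
  per cell ``{step, cell_id, substrate}``, fixed key order, full float
  precision;
- trajectory: TSV with one header line and a fixed column order;
- genealogy: TSV with columns
  ``step  event  rep_id  rtype  template_id  catalyst_id  cell_id``
  (template/catalyst empty on death rows), plus a companion cell-event TSV
  ``step  event  cell_id  daughter_a  daughter_b`` for divisions/removals.

The fixture generator builds synthetic population snapshots with exactly
prescribed between-cell and within-cell trait variance, for testing the
moment estimators without running long simulations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .params import Params
from .population import RunLogs, TRAJECTORY_COLUMNS
from .world import Snapshot, TYPE_NAMES

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "write_snapshots",
    "read_snapshots",
    "write_trajectory",
    "read_trajectory",
    "write_genealogy",
    "read_genealogy",
    "write_cell_events",
    "read_cell_events",
    "FixtureSpec",
    "generate_fixture",
]


# -- configuration -----------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters plus the analysis window; round-trips losslessly to YAML."""

    params: Params
    analysis_window: tuple[int, int] | None = None


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Defaults are applied by :class:`Params` (``d=0.02``, ``delta_mut=0.05``,
    ``k_max=1``, ``n_tot=50*V``, ``init_cells=50``); unknown keys raise with
    a field-level message.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} is not a mapping")
    window = data.pop("analysis_window", None)
    params = Params.from_dict(data)
    if window is not None:
        if not (isinstance(window, (list, tuple)) and len(window) == 2):
            raise ValueError("analysis_window must be a [t0, t1] pair")
        window = (int(window[0]), int(window[1]))
    return RunConfig(params=params, analysis_window=window)


def dump_config(cfg: RunConfig, path) -> None:
    data = cfg.params.to_dict()
    if cfg.analysis_window is not None:
        data["analysis_window"] = list(cfg.analysis_window)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# -- snapshots (JSONL) -------------------------------------------------------


def write_snapshots(snapshots, path, mode: str = "w") -> None:
    """Write one or more snapshots as JSONL (fixed key order)."""
    if isinstance(snapshots, Snapshot):
        snapshots = [snapshots]
    with open(path, mode) as fh:
        for snap in snapshots:
            for i in range(snap.n_replicators):
                rec = {
                    "step": int(snap.step),
                    "cell_id": int(snap.cell_uid[i]),
                    "rep_id": int(snap.rep_id[i]),
                    "rtype": TYPE_NAMES[snap.rtype[i]],
                    "k": [float(x) for x in snap.profile[i]],
                    "state": "free",
                }
                fh.write(json.dumps(rec) + "\n")
            for j in range(snap.n_cells):
                rec = {
                    "step": int(snap.step),
                    "cell_id": int(snap.cells[j]),
                    "substrate": int(snap.substrate[j]),
                }
                fh.write(json.dumps(rec) + "\n")


def read_snapshots(path) -> list[Snapshot]:
    """Read a JSONL snapshot file back into :class:`Snapshot` objects."""
    by_step: dict[int, dict[str, list]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            step = int(rec["step"])
            bucket = by_step.setdefault(
                step,
                {"rep_id": [], "cell_uid": [], "rtype": [], "k": [],
                 "cells": [], "substrate": []},
            )
            if "rep_id" in rec:
                bucket["rep_id"].append(rec["rep_id"])
                bucket["cell_uid"].append(rec["cell_id"])
                bucket["rtype"].append(TYPE_NAMES.index(rec["rtype"]))
                bucket["k"].append(rec["k"])
            else:
                bucket["cells"].append(rec["cell_id"])
                bucket["substrate"].append(rec["substrate"])
    out = []
    for step in sorted(by_step):
        b = by_step[step]
        out.append(Snapshot(
            step=step,
            rep_id=np.array(b["rep_id"], dtype=np.int64),
            cell_uid=np.array(b["cell_uid"], dtype=np.int64),
            rtype=np.array(b["rtype"], dtype=np.int8),
            profile=np.array(b["k"], dtype=np.float64).reshape(len(b["k"]), 8),
            cells=np.array(b["cells"], dtype=np.int64),
            substrate=np.array(b["substrate"], dtype=np.int64),
        ))
    return out


# -- trajectory (TSV) --------------------------------------------------------


def write_trajectory(trajectory: pd.DataFrame, path) -> None:
    trajectory.to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    return df


# -- genealogy (TSV) ---------------------------------------------------------

_GENEALOGY_HEADER = "step\tevent\trep_id\trtype\ttemplate_id\tcatalyst_id\tcell_id"


def write_genealogy(logs: RunLogs, path) -> None:
    """Replicator-level birth/death event log, ordered by step."""
    rows = []
    for step, child, rt, tmpl, cat, cell in logs.births:
        rows.append((int(step), 0, int(child), int(rt), str(int(tmpl)),
                     str(int(cat)), int(cell)))
    for step, rep, rt, cell in logs.deaths:
        rows.append((int(step), 1, int(rep), int(rt), "", "", int(cell)))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write(_GENEALOGY_HEADER + "\n")
        for step, ev, rep, rt, tmpl, cat, cell in rows:
            name = "birth" if ev == 0 else "death"
            fh.write(f"{step}\t{name}\t{rep}\t{TYPE_NAMES[rt]}\t{tmpl}\t{cat}\t{cell}\n")


def read_genealogy(path) -> RunLogs:
    """Rebuild a :class:`RunLogs` (births/deaths only) from a genealogy TSV."""
    births, deaths = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _GENEALOGY_HEADER:
            raise ValueError(f"unexpected genealogy header: {header!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            step, event, rep, rt, tmpl, cat, cell = parts
            rt_i = TYPE_NAMES.index(rt)
            if event == "birth":
                births.append((int(step), int(rep), rt_i, int(tmpl),
                               int(cat), int(cell)))
            elif event == "death":
                deaths.append((int(step), int(rep), rt_i, int(cell)))
            else:
                raise ValueError(f"unknown event type {event!r}")
    logs = RunLogs(log_genealogy=True)
    if births:
        births.sort(key=lambda r: r[1])  # child ids are birth-ordered
        logs.record_births(np.array(births, dtype=np.int64))
    if deaths:
        logs.record_deaths(np.array(deaths, dtype=np.int64))
    return logs


_CELL_HEADER = "step\tevent\tcell_id\tdaughter_a\tdaughter_b"


def write_cell_events(logs: RunLogs, path) -> None:
    """Cell-level division/removal log (companion to the genealogy TSV)."""
    rows = []
    for step, parent, da, db in logs.divisions:
        rows.append((int(step), "division", int(parent), str(int(da)), str(int(db))))
    for step, uid in logs.removals:
        rows.append((int(step), "removal", int(uid), "", ""))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write(_CELL_HEADER + "\n")
        for step, ev, cell, da, db in rows:
            fh.write(f"{step}\t{ev}\t{cell}\t{da}\t{db}\n")


def read_cell_events(path) -> RunLogs:
    logs = RunLogs(log_genealogy=True)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _CELL_HEADER:
            raise ValueError(f"unexpected cell-event header: {header!r}")
        for line in fh:
            step, ev, cell, da, db = line.rstrip("\n").split("\t")
            if ev == "division":
                logs.record_division(int(step), int(cell), int(da), int(db))
            elif ev == "removal":
                logs.record_removals(int(step), np.array([int(cell)], dtype=np.int64))
            else:
                raise ValueError(f"unknown cell event {ev!r}")
    return logs


# -- synthetic fixtures ------------------------------------------------------


@dataclass
class FixtureSpec:
    """Recipe for a synthetic snapshot with prescribed trait moments.

    The generated population has between-cell trait variance exactly
    ``sigma2_cel`` and mean within-cell variance exactly ``sigma2_mol``
    (two-point constructions at both levels), with all eight profile
    entries of a replicator equal to its trait value.
    """

    n_cells: int = 50
    cell_size: int = 100
    sigma2_cel: float = 0.0
    sigma2_mol: float = 0.0
    mean_trait: float = 0.5
    k_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.cell_size < 1:
            raise ValueError("n_cells and cell_size must be positive")
        if self.sigma2_cel < 0 or self.sigma2_mol < 0:
            raise ValueError("target variances must be nonnegative")
        if self.sigma2_cel > 0 and self.n_cells % 2:
            raise ValueError("sigma2_cel > 0 requires an even n_cells")
        if self.sigma2_mol > 0 and self.cell_size % 2:
            raise ValueError("sigma2_mol > 0 requires an even cell_size")
        spread = math.sqrt(self.sigma2_cel) + math.sqrt(self.sigma2_mol)
        if self.mean_trait - spread < 0 or self.mean_trait + spread > self.k_max:
            raise ValueError(
                f"targets unattainable: mean {self.mean_trait} +/- {spread:.4g} "
                f"leaves the [0, {self.k_max}] box"
            )


def generate_fixture(spec: FixtureSpec, rng: np.random.Generator | None = None) -> Snapshot:
    """Build the synthetic snapshot described by ``spec``.

    Deterministic for a fixed ``spec.seed`` (an explicit ``rng`` overrides
    it).  Half the cells sit at ``mean + a`` and half at ``mean - a`` with
    ``a = sqrt(sigma2_cel)``; within every cell, half the replicators sit at
    the cell mean ``+ b`` and half at ``- b`` with ``b = sqrt(sigma2_mol)``.
    Cell-level and within-cell assignments are shuffled with the RNG; types
    alternate P, Q within each cell; substrate is zero.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    a = math.sqrt(spec.sigma2_cel)
    b = math.sqrt(spec.sigma2_mol)
    nc, sz = spec.n_cells, spec.cell_size

    cell_offsets = np.concatenate([np.full(nc // 2, a), np.full(nc - nc // 2, -a)])
    rng.shuffle(cell_offsets)
    traits = np.empty(nc * sz)
    for c in range(nc):
        within = np.concatenate([np.full(sz // 2, b), np.full(sz - sz // 2, -b)])
        rng.shuffle(within)
        traits[c * sz:(c + 1) * sz] = spec.mean_trait + cell_offsets[c] + within

    n = nc * sz
    return Snapshot(
        step=0,
        rep_id=np.arange(n, dtype=np.int64),
        cell_uid=np.repeat(np.arange(nc, dtype=np.int64), sz),
        rtype=(np.tile(np.arange(sz), nc) % 2).astype(np.int8),
        profile=np.repeat(traits[:, None], 8, axis=1),
        cells=np.arange(nc, dtype=np.int64),
        substrate=np.zeros(nc, dtype=np.int64),
    )
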