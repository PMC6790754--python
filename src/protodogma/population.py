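"""World-level scheduler: reaction over cells, substrate diffusion, division.

One time step is three substeps, in fixed order:

1. **reaction** — per cell: complex formation -> substrate-limited synthesis
   (with mutation) -> decay (see :mod:`protodogma.kinetics`);
2. **diffusion** — all substrate is re-distributed multinomially among cells
   with probabilities proportional to each cell's replicator count
   (substrate diffuses much faster than replicators, which never move);
3. **cell division** — every cell with more than ``V`` particles splits,
   each particle (replicator or substrate unit) going to either daughter
   with probability 1/2; cells with zero particles are then removed.

Total particle number ``n_tot`` is conserved exactly and checked at every
step boundary.  The unit of time is set by decay: one replicator decays with
probability ``d`` per step, so the mean replicator lifetime is ``1/d`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import Params
from .world import PROFILE_COLUMNS, Snapshot, World, init_world
from . import kinetics

__all__ = [
    "RunLogs",
    "RunResult",
    "TRAJECTORY_COLUMNS",
    "diffuse_substrate",
    "divide_and_cull",
    "step",
    "run",
    "continue_run",
    "replicator_lifetimes",
]

TRAJECTORY_COLUMNS = (
    ("step",)
    + PROFILE_COLUMNS
    + ("cell_count", "freq_P", "freq_Q", "freq_S", "mean_minority")
)


class RunLogs:
    """Event logs of one run, accumulated as per-step array chunks.

    Birth/death/division events are recorded only if ``log_genealogy`` is
    on; mutation increments only if ``log_mutations`` is on.
    """

    def __init__(self, log_genealogy: bool = True, log_mutations: bool = False):
        self.log_genealogy = log_genealogy
        self.log_mutations = log_mutations
        self._births: list[np.ndarray] = []  # (k, 6) step, child, rtype, tmpl, cat, cell_uid
        self._deaths: list[np.ndarray] = []  # (k, 4) step, rep_id, rtype, cell_uid
        self._divisions: list[np.ndarray] = []  # (k, 4) step, parent, daughter_a, daughter_b
        self._removals: list[np.ndarray] = []  # (k, 2) step, cell_uid
        self._mut_pre: list[np.ndarray] = []
        self._mut_inc: list[np.ndarray] = []

    # -- recording -------------------------------------------------------

    def record_births(self, arr: np.ndarray) -> None:
        if self.log_genealogy and arr.size:
            self._births.append(arr)

    def record_deaths(self, arr: np.ndarray) -> None:
        if self.log_genealogy and arr.size:
            self._deaths.append(arr)

    def record_division(self, step: int, parent: int, da: int, db: int) -> None:
        if self.log_genealogy:
            self._divisions.append(np.array([[step, parent, da, db]], dtype=np.int64))

    def record_removals(self, step: int, uids: np.ndarray) -> None:
        if self.log_genealogy and uids.size:
            arr = np.column_stack([np.full(uids.size, step, dtype=np.int64), uids])
            self._removals.append(arr)

    def record_mutations(self, pre: np.ndarray, inc: np.ndarray) -> None:
        if self.log_mutations and pre.size:
            self._mut_pre.append(pre)
            self._mut_inc.append(inc)

    # -- access ----------------------------------------------------------

    @staticmethod
    def _stack(chunks: list[np.ndarray], ncol: int) -> np.ndarray:
        if not chunks:
            return np.empty((0, ncol), dtype=np.int64)
        return np.concatenate(chunks, axis=0)

    @property
    def births(self) -> np.ndarray:
        """(n, 6) int64: step, child_id, child_rtype, template_id, catalyst_id, cell_uid."""
        return self._stack(self._births, 6)

    @property
    def deaths(self) -> np.ndarray:
        """(n, 4) int64: step, rep_id, rtype, cell_uid."""
        return self._stack(self._deaths, 4)

    @property
    def divisions(self) -> np.ndarray:
        """(n, 4) int64: step, parent_uid, daughter_a_uid, daughter_b_uid."""
        return self._stack(self._divisions, 4)

    @property
    def removals(self) -> np.ndarray:
        """(n, 2) int64: step, cell_uid."""
        return self._stack(self._removals, 2)

    @property
    def mutation_pre(self) -> np.ndarray:
        return np.concatenate(self._mut_pre) if self._mut_pre else np.empty(0)

    @property
    def mutation_increments(self) -> np.ndarray:
        return np.concatenate(self._mut_inc) if self._mut_inc else np.empty(0)


@dataclass
class RunResult:
    params: Params
    trajectory: pd.DataFrame
    world: World
    snapshots: list[Snapshot]
    logs: RunLogs
    stopped_early: str | None = None

    @property
    def final_snapshot(self) -> Snapshot:
        return self.snapshots[-1]


# -- substeps ----------------------------------------------------------------


def diffuse_substrate(world: World, rng: np.random.Generator) -> None:
    """Redistribute all substrate multinomially, cell weights = replicator
    counts.  Cells without replicators receive nothing.  If no replicators
    exist at all, substrate stays where it is (degenerate world)."""
    s_tot = int(world.substrate.sum())
    if s_tot == 0:
        return
    counts = world.rep_counts_per_cell()
    n_rep = counts.sum()
    if n_rep == 0:
        return
    world.substrate = rng.multinomial(s_tot, counts / n_rep).astype(np.int64)


def divide_and_cull(world: World, rng: np.random.Generator,
                    logs: RunLogs | None = None, step_no: int | None = None) -> None:
    """Split every cell with more than ``V`` particles; drop empty cells.

    Each particle of a dividing cell — replicator or substrate unit — is
    independently assigned to daughter A or B with probability 1/2.  Both
    daughters get fresh uids; the parent uid is retired (recorded in the
    division log so the cell genealogy stays complete).
    """
    V = world.params.V
    if step_no is None:
        step_no = world.step_count
    counts = world.rep_counts_per_cell()
    particles = counts + world.substrate
    dividing = np.nonzero(particles > V)[0]

    if dividing.size:
        new_uids: list[int] = []
        new_sub: list[int] = []
        base = world.n_cells
        for j, c in enumerate(dividing):
            idx = np.nonzero(world.cell_ix == c)[0]
            to_b = rng.random(idx.size) < 0.5
            s_b = int(rng.binomial(world.substrate[c], 0.5))
            uid_a = world.next_cell_uid
            uid_b = world.next_cell_uid + 1
            world.next_cell_uid += 2
            parent = int(world.cell_uid[c])
            world.cell_uid[c] = uid_a
            world.substrate[c] -= s_b
            world.cell_ix[idx[to_b]] = base + j
            new_uids.append(uid_b)
            new_sub.append(s_b)
            if logs is not None:
                logs.record_division(step_no, parent, uid_a, uid_b)
        world.cell_uid = np.concatenate([world.cell_uid, np.array(new_uids, dtype=np.int64)])
        world.substrate = np.concatenate([world.substrate, np.array(new_sub, dtype=np.int64)])

    counts = world.rep_counts_per_cell()
    particles = counts + world.substrate
    keep = particles > 0
    if not keep.all():
        if logs is not None:
            logs.record_removals(step_no, world.cell_uid[~keep])
        new_index = np.cumsum(keep) - 1
        world.cell_ix = new_index[world.cell_ix].astype(np.int32)
        world.cell_uid = world.cell_uid[keep]
        world.substrate = world.substrate[keep]


def step(world: World, logs: RunLogs | None = None) -> None:
    """Advance the world by one full time step (reaction, diffusion, division)."""
    p = world.params
    step_no = world.step_count + 1

    (dead, c_prof, c_rtype, c_cell, c_tmpl, c_cat, c_dead,
     mut_pre, mut_inc, _ncx) = kinetics.reaction_substep(
        world.cell_ix, world.rtype, world.profile, world.substrate,
        p.m, p.delta_mut, p.k_max, p.d,
        logs.log_mutations if logs is not None else False,
    )

    n_children = c_rtype.size
    child_ids = np.arange(world.next_rep_id, world.next_rep_id + n_children, dtype=np.int64)
    world.next_rep_id += n_children

    if logs is not None:
        logs.record_mutations(mut_pre, mut_inc)
        if logs.log_genealogy:
            if n_children:
                births = np.column_stack([
                    np.full(n_children, step_no, dtype=np.int64),
                    child_ids,
                    c_rtype.astype(np.int64),
                    world.rep_id[c_tmpl],
                    world.rep_id[c_cat],
                    world.cell_uid[c_cell],
                ])
                logs.record_births(births)
            dead_resident = np.nonzero(dead)[0]
            dead_child = np.nonzero(c_dead)[0]
            n_dead = dead_resident.size + dead_child.size
            if n_dead:
                deaths = np.empty((n_dead, 4), dtype=np.int64)
                k = dead_resident.size
                deaths[:k, 1] = world.rep_id[dead_resident]
                deaths[:k, 2] = world.rtype[dead_resident]
                deaths[:k, 3] = world.cell_uid[world.cell_ix[dead_resident]]
                deaths[k:, 1] = child_ids[dead_child]
                deaths[k:, 2] = c_rtype[dead_child]
                deaths[k:, 3] = world.cell_uid[c_cell[dead_child]]
                deaths[:, 0] = step_no
                logs.record_deaths(deaths)

    # compact survivors + surviving newborns
    keep = ~dead
    ckeep = ~c_dead
    world.rep_id = np.concatenate([world.rep_id[keep], child_ids[ckeep]])
    world.rtype = np.concatenate([world.rtype[keep], c_rtype[ckeep]])
    world.cell_ix = np.concatenate([world.cell_ix[keep], c_cell[ckeep]])
    world.birth_step = np.concatenate([
        world.birth_step[keep],
        np.full(int(ckeep.sum()), step_no, dtype=np.int32),
    ])
    world.profile = np.concatenate([world.profile[keep], c_prof[ckeep]], axis=0)

    diffuse_substrate(world, world.rng)
    divide_and_cull(world, world.rng, logs, step_no)

    world.step_count = step_no
    world.check_conservation()


# -- trajectory recording ----------------------------------------------------


def _trajectory_record(world: World) -> tuple:
    n = world.n_replicators
    p = world.params
    if n:
        means = world.profile.mean(axis=0)
        n_q = int(world.rtype.sum())
        n_p = n - n_q
    else:
        means = np.full(8, np.nan)
        n_p = n_q = 0
    s_tot = int(world.substrate.sum())
    counts = world.rep_counts_per_cell()
    particles = counts + world.substrate
    eligible = (particles >= p.V / 2) & (counts > 0)
    if eligible.any():
        q_per_cell = np.bincount(
            world.cell_ix, weights=world.rtype.astype(np.float64),
            minlength=world.n_cells,
        )
        p_per_cell = counts - q_per_cell
        mino = np.minimum(p_per_cell[eligible], q_per_cell[eligible]) / counts[eligible]
        mean_minority = float(mino.mean())
    else:
        mean_minority = np.nan
    return (
        (world.step_count, *means, world.n_cells,
         n_p / p.n_tot, n_q / p.n_tot, s_tot / p.n_tot, mean_minority)
    )


def _simulate(world: World, t_steps: int, logs: RunLogs,
              record_every: int, snapshot_every: int) -> RunResult:
    params = world.params
    t_end = world.step_count + t_steps
    records = [_trajectory_record(world)]
    snapshots = [world.snapshot()]
    stopped = None
    for _ in range(t_steps):
        step(world, logs)
        t = world.step_count
        if t % record_every == 0 and t != t_end:
            records.append(_trajectory_record(world))
        if snapshot_every and t % snapshot_every == 0 and t != t_end:
            snapshots.append(world.snapshot())
        if world.n_replicators == 0:
            stopped = f"all replicators extinct at step {t}"
            break

    records.append(_trajectory_record(world))
    snapshots.append(world.snapshot())
    trajectory = pd.DataFrame.from_records(records, columns=TRAJECTORY_COLUMNS)
    # drop a duplicated row if the final step landed on a cadence boundary
    trajectory = trajectory.drop_duplicates(subset="step", keep="last", ignore_index=True)
    return RunResult(params, trajectory, world, snapshots, logs, stopped)


def run(params: Params) -> RunResult:
    """Run a full simulation; bit-reproducible for a given (seed, params).

    Trajectory rows are written at step 0, every ``record_every`` steps, and
    at the final step.  Snapshots are kept at step 0, every
    ``snapshot_every`` steps (if nonzero), and at the final step.  If every
    replicator dies the run stops early (legitimate absorbing state).
    """
    rng = np.random.default_rng(params.seed)
    kinetics.seed_kernel(int(rng.integers(2**31)))
    world = init_world(params, rng)
    logs = RunLogs(params.log_genealogy, params.log_mutations)
    return _simulate(world, params.t_max, logs, params.record_every,
                     params.snapshot_every)


def continue_run(world: World, t_steps: int, log_genealogy: bool = True,
                 log_mutations: bool = False, record_every: int | None = None,
                 snapshot_every: int | None = None) -> RunResult:
    """Continue an evolved world for ``t_steps`` more steps with fresh logs.

    Useful for attaching an event-logged tail segment (e.g. for ancestor
    tracking) to a long run simulated without logging.  RNG state carries
    over, so ``run`` followed by ``continue_run`` reproduces a single longer
    ``run`` with the same seed.
    """
    p = world.params
    logs = RunLogs(log_genealogy, log_mutations)
    return _simulate(world, t_steps, logs,
                     p.record_every if record_every is None else record_every,
                     p.snapshot_every if snapshot_every is None else snapshot_every)


def replicator_lifetimes(logs: RunLogs, final_world: World | None = None) -> np.ndarray:
    """Completed lifetimes, in decay trials, of all dead replicators.

    A replicator born during step ``b`` faces its first decay trial in that
    same step; founders (birth step 0) face theirs in step 1.  A death in
    step ``t`` therefore completes ``t - b + 1`` trials (founders: ``t``),
    which is geometrically distributed with per-trial hazard ``d``.
    Replicators still alive at the end are censored and excluded.
    """
    deaths = logs.deaths
    if deaths.size == 0:
        return np.empty(0, dtype=np.int64)
    births = logs.births
    t = deaths[:, 0]
    ids = deaths[:, 1]
    b = np.zeros(ids.size, dtype=np.int64)
    if births.size:
        # child ids are assigned in increasing step order, so births[:, 1] is sorted
        pos = np.searchsorted(births[:, 1], ids)
        pos_c = np.minimum(pos, births.shape[0] - 1)
        found = births[pos_c, 1] == ids
        b[found] = births[pos_c[found], 0]
    return t - b + (b > 0)
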