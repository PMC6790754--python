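"""Domain state: replicators, protocells, the world, and snapshots.

Replicators carry a heritable profile of eight catalytic activities
``k[c][p][t]`` with ``c, p, t`` in {P, Q}: the four ``c = own type`` entries
are the replicator's own activities, the other four are the activities its
transcripts would have.  The entry ``k[c][p][t]`` is the rate constant with
which a type-``c`` catalyst forms a complex producing a type-``p`` replicator
from a type-``t`` template.  Entries may drift below zero (the corresponding
rate is then zero) but never exceed ``k_max``.

For performance the world is stored as flat numpy arrays (struct-of-arrays),
not per-replicator objects:

- ``rep_id``     int64 (n,)    globally unique, never reused
- ``rtype``      int8  (n,)    0 = P, 1 = Q
- ``cell_ix``    int32 (n,)    index into the cell arrays
- ``birth_step`` int32 (n,)    0 for founders
- ``profile``    float64 (n, 8)  entries in the fixed order below
- ``cell_uid``   int64 (n_cells,)  persistent protocell identity
- ``substrate``  int64 (n_cells,)  S count per protocell

Profile entry order (fixed everywhere, including snapshots):
``[c=P: (pp, pq, qp, qq), c=Q: (pp, pq, qp, qq)]`` i.e. index
``4*c + 2*p + t`` with P = 0, Q = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Params

__all__ = [
    "P",
    "Q",
    "TYPE_NAMES",
    "PROFILE_COLUMNS",
    "profile_index",
    "effective_rate",
    "World",
    "Snapshot",
    "init_world",
]

P: int = 0
Q: int = 1
TYPE_NAMES = ("P", "Q")

#: Column names for the 8 profile entries in storage order.
PROFILE_COLUMNS = tuple(
    f"k{TYPE_NAMES[c]}_{TYPE_NAMES[p]}{TYPE_NAMES[t]}"
    for c in (P, Q)
    for p in (P, Q)
    for t in (P, Q)
)


def profile_index(c: int, p: int, t: int) -> int:
    """Flat index of entry ``k[c][p][t]`` in the 8-vector profile."""
    return 4 * c + 2 * p + t


def effective_rate(k: float, k_max: float) -> float:
    """Rate constant actually used for complex formation.

    Heritable values may drift below zero; the chemistry then treats them as
    zero.  A value above ``k_max`` indicates profile corruption (the mutation
    boundary is reflecting) and raises.
    """
    if k > k_max:
        raise ValueError(f"profile entry {k} exceeds k_max={k_max}")
    return k if k > 0.0 else 0.0


@dataclass
class Snapshot:
    """Immutable copy of the replicator/cell state at one step."""

    step: int
    rep_id: np.ndarray  # int64 (n,)
    cell_uid: np.ndarray  # int64 (n,) per replicator
    rtype: np.ndarray  # int8 (n,)
    profile: np.ndarray  # float64 (n, 8)
    cells: np.ndarray  # int64 (n_cells,) cell uids
    substrate: np.ndarray  # int64 (n_cells,)

    @property
    def n_replicators(self) -> int:
        return int(self.rep_id.size)

    @property
    def n_cells(self) -> int:
        return int(self.cells.size)

    def particle_total(self) -> int:
        return int(self.rep_id.size + self.substrate.sum())


class World:
    """Full population state plus id counters and RNG.

    Invariant: ``n_replicators + sum(substrate) == params.n_tot`` at every
    step boundary (checked by the scheduler).
    """

    def __init__(self, params: Params, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.step_count: int = 0
        n = 0
        self.rep_id = np.empty(n, dtype=np.int64)
        self.rtype = np.empty(n, dtype=np.int8)
        self.cell_ix = np.empty(n, dtype=np.int32)
        self.birth_step = np.empty(n, dtype=np.int32)
        self.profile = np.empty((n, 8), dtype=np.float64)
        self.cell_uid = np.empty(0, dtype=np.int64)
        self.substrate = np.empty(0, dtype=np.int64)
        self.next_rep_id: int = 0
        self.next_cell_uid: int = 0

    # -- bookkeeping -----------------------------------------------------

    @property
    def n_replicators(self) -> int:
        return int(self.rep_id.size)

    @property
    def n_cells(self) -> int:
        return int(self.cell_uid.size)

    def particle_total(self) -> int:
        return int(self.rep_id.size + self.substrate.sum())

    def check_conservation(self) -> None:
        total = self.particle_total()
        if total != self.params.n_tot:
            raise RuntimeError(
                f"particle conservation violated at step {self.step_count}: "
                f"{total} != n_tot={self.params.n_tot}"
            )

    def rep_counts_per_cell(self) -> np.ndarray:
        return np.bincount(self.cell_ix, minlength=self.n_cells).astype(np.int64)

    def snapshot(self) -> Snapshot:
        return Snapshot(
            step=self.step_count,
            rep_id=self.rep_id.copy(),
            cell_uid=self.cell_uid[self.cell_ix].copy(),
            rtype=self.rtype.copy(),
            profile=self.profile.copy(),
            cells=self.cell_uid.copy(),
            substrate=self.substrate.copy(),
        )


def init_world(params: Params, rng: np.random.Generator) -> World:
    """Construct the initial world.

    ``init_cells`` protocells of equal size share ``n_tot`` replicators;
    substrate starts at zero; every profile entry starts at ``k_max`` so the
    two types are initially indistinguishable.  Within each cell, types
    alternate (P, Q, P, ...) so the global P:Q imbalance is at most
    ``init_cells`` and the per-cell imbalance at most 1.

    If ``n_tot`` is not divisible by ``init_cells`` the remainder replicators
    are spread one-per-cell over the first cells, keeping the total exact.
    """
    w = World(params, rng)
    nc = params.init_cells
    base, rem = divmod(params.n_tot, nc)
    sizes = np.full(nc, base, dtype=np.int64)
    sizes[:rem] += 1
    n = int(sizes.sum())
    assert n == params.n_tot

    w.cell_uid = np.arange(nc, dtype=np.int64)
    w.substrate = np.zeros(nc, dtype=np.int64)
    w.next_cell_uid = nc

    w.rep_id = np.arange(n, dtype=np.int64)
    w.next_rep_id = n
    w.cell_ix = np.repeat(np.arange(nc, dtype=np.int32), sizes)
    # alternate types within each cell: position parity within the cell
    pos_in_cell = np.concatenate([np.arange(s, dtype=np.int64) for s in sizes])
    w.rtype = (pos_in_cell % 2).astype(np.int8)
    w.birth_step = np.zeros(n, dtype=np.int32)
    w.profile = np.full((n, 8), params.k_max, dtype=np.float64)
    w.check_conservation()
    return w
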