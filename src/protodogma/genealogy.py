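"""Two-level ancestor tracking: protocell lineages and template lineages.

Once catalytic/informatic symmetry has broken, information is transmitted
almost exclusively through template-type replicators: tracing the surviving
population back in time, the common ancestors are nearly always templates,
even though catalysts are the majority of the population.  That contrast is
the ancestor role spectrum computed here.

Tracking is two-stage: first the common ancestors of all surviving
*protocells* are found on the cell division tree; molecular (template)
lineages are then restricted to replicators contained in those cells.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .population import RunLogs, RunResult
from .world import Snapshot

__all__ = [
    "CellTree",
    "MolecularLineage",
    "common_ancestor_cells",
    "trace_replicator_ancestors",
    "RoleSpectrum",
    "ancestor_role_spectrum",
]


@dataclass
class CellTree:
    """Protocell genealogy: parent map plus lifetimes.

    ``parent[uid]`` is the parent cell uid (-1 for a founding cell);
    ``birth[uid]`` is the step at which the cell appeared (0 for founders);
    ``end[uid]`` is the step at which it divided or was removed (division
    retires the parent uid: both daughters get fresh uids), or ``None`` if
    the cell is still alive.
    """

    parent: dict[int, int] = field(default_factory=dict)
    birth: dict[int, int] = field(default_factory=dict)
    end: dict[int, int | None] = field(default_factory=dict)
    alive: set[int] = field(default_factory=set)

    @classmethod
    def from_logs(cls, logs: RunLogs, alive_uids: np.ndarray,
                  founders, founder_birth: int = 0) -> "CellTree":
        """Build the tree from division/removal logs and the final alive set.

        ``founders`` is the count of initial cells (uids ``0..n-1``) or an
        explicit iterable of founding cell uids (e.g. the cells present when
        logging started mid-run).
        """
        tree = cls()
        if isinstance(founders, (int, np.integer)):
            founders = range(int(founders))
        for uid in founders:
            uid = int(uid)
            tree.parent[uid] = -1
            tree.birth[uid] = founder_birth
            tree.end[uid] = None
        for step, parent, da, db in logs.divisions:
            step, parent, da, db = int(step), int(parent), int(da), int(db)
            if parent not in tree.parent:
                raise ValueError(f"division log references unknown cell {parent}")
            tree.end[parent] = step
            for d in (da, db):
                tree.parent[d] = parent
                tree.birth[d] = step
                tree.end[d] = None
        for step, uid in logs.removals:
            tree.end[int(uid)] = int(step)
        tree.alive = {int(u) for u in alive_uids}
        for uid in tree.alive:
            if uid not in tree.parent:
                raise ValueError(f"alive cell {uid} missing from division log")
        return tree

    def ancestors_of(self, uid: int) -> list[int]:
        """Path from ``uid`` (inclusive) back to its founding cell."""
        path = []
        seen = set()
        while uid != -1:
            if uid in seen:
                raise ValueError(f"cycle in cell tree at {uid}")
            seen.add(uid)
            path.append(uid)
            uid = self.parent[uid]
        return path

    def alive_at(self, uid: int, step: int) -> bool:
        end = self.end.get(uid)
        return self.birth[uid] <= step and (end is None or end > step)


def common_ancestor_cells(tree: CellTree, at_step: int) -> set[int]:
    """Cells alive at ``at_step`` that are ancestral to *all* surviving cells.

    A surviving cell counts as its own ancestor.  The set may be empty if
    the surviving cells have not yet coalesced by ``at_step``.
    """
    if not tree.alive:
        raise ValueError("no surviving cells")
    common: set[int] | None = None
    for uid in tree.alive:
        anc = set(tree.ancestors_of(uid))
        common = anc if common is None else (common & anc)
    assert common is not None
    return {uid for uid in common if tree.alive_at(uid, at_step)}


@dataclass
class MolecularLineage:
    """Template-parent genealogy of replicators.

    Backed by flat arrays indexed by ``rep_id - id_offset`` (ids are
    assigned densely in birth order, so a logged segment of a longer run
    occupies a contiguous id range).  ``parent`` is -1 for founders —
    replicators already alive when logging started; ``death`` is -1 for
    replicators still alive at the end.
    """

    parent: np.ndarray  # int64 (n_ids,)
    birth: np.ndarray  # int64 (n_ids,)
    death: np.ndarray  # int64 (n_ids,)
    rtype: np.ndarray  # int8 (n_ids,)
    known: np.ndarray  # bool (n_ids,) id appears in logs or founder set
    id_offset: int = 0

    def _ix(self, rep_id: int) -> int:
        ix = rep_id - self.id_offset
        if ix < 0 or ix >= self.known.size or not self.known[ix]:
            raise KeyError(f"genealogy gap: replicator {rep_id} has no record")
        return ix

    @classmethod
    def from_logs(cls, logs: RunLogs, founder_ids, next_rep_id: int,
                  founder_rtype: np.ndarray | None = None,
                  founder_birth: np.ndarray | None = None) -> "MolecularLineage":
        """``founder_ids`` is a count (ids ``0..n-1``) or an id array."""
        if isinstance(founder_ids, (int, np.integer)):
            founder_ids = np.arange(int(founder_ids), dtype=np.int64)
        else:
            founder_ids = np.asarray(founder_ids, dtype=np.int64)
        offset = int(founder_ids.min()) if founder_ids.size else 0
        n = next_rep_id - offset
        parent = np.full(n, -1, dtype=np.int64)
        birth = np.zeros(n, dtype=np.int64)
        death = np.full(n, -1, dtype=np.int64)
        rtype = np.zeros(n, dtype=np.int8)
        known = np.zeros(n, dtype=bool)
        known[founder_ids - offset] = True
        if founder_rtype is not None:
            rtype[founder_ids - offset] = founder_rtype
        else:
            rtype[founder_ids - offset] = np.arange(founder_ids.size) % 2
        if founder_birth is not None:
            birth[founder_ids - offset] = founder_birth
        b = logs.births
        if b.size:
            ids = b[:, 1] - offset
            known[ids] = True
            birth[ids] = b[:, 0]
            rtype[ids] = b[:, 2]
            parent[ids] = b[:, 3]
        d = logs.deaths
        if d.size:
            death[d[:, 1] - offset] = d[:, 0]
        return cls(parent, birth, death, rtype, known, offset)

    @classmethod
    def from_result(cls, result: RunResult) -> "MolecularLineage":
        """Lineage of a logged run (or logged tail segment of a run).

        The founders are the replicators present in the first snapshot of
        the result, with their true birth steps.
        """
        first = result.snapshots[0]
        founder_birth = None
        if first.step > 0:
            # continuation segment: founders predate the logs; date them at
            # the segment start (an upper bound on their true birth)
            founder_birth = np.full(first.n_replicators, first.step,
                                    dtype=np.int64)
        return cls.from_logs(result.logs, first.rep_id,
                             result.world.next_rep_id,
                             founder_rtype=first.rtype,
                             founder_birth=founder_birth)

    def get_parent(self, rep_id: int) -> int:
        return int(self.parent[self._ix(rep_id)])

    def get_birth(self, rep_id: int) -> int:
        return int(self.birth[self._ix(rep_id)])

    def get_rtype(self, rep_id: int) -> int:
        return int(self.rtype[self._ix(rep_id)])

    def alive_in_window(self, rep_id: int, t0: int, t1: int) -> bool:
        ix = self._ix(rep_id)
        b = int(self.birth[ix])
        d = int(self.death[ix])
        return b <= t1 and (d == -1 or d >= t0)


def trace_replicator_ancestors(
    lineage: MolecularLineage,
    focal: np.ndarray,
    window: tuple[int, int],
    members: set[int] | None = None,
) -> Counter:
    """Template-ancestors of the focal replicators within a time window.

    For each focal replicator (born after the window), walk up the template
    genealogy to the unique lineage member whose lifetime intersects
    ``[t0, t1]``; the returned multiset counts how many focal replicators
    coalesce on each ancestor.  A focal replicator alive within the window
    is its own ancestor.  If ``members`` is given (e.g. the replicators
    contained in common-ancestor cells during the window), ancestors outside
    that set are dropped.

    Raises ``KeyError`` naming the id if the genealogy has a gap.
    """
    t0, t1 = window
    if t0 > t1:
        raise ValueError("empty window")
    out: Counter = Counter()
    for rid in focal:
        rid = int(rid)
        cur = rid
        while True:
            if cur < 0:
                raise KeyError(
                    f"genealogy gap: lineage of focal {rid} ran out of records"
                )
            if lineage.get_birth(cur) <= t1:
                break
            cur = lineage.get_parent(cur)
        if not lineage.alive_in_window(cur, t0, t1):
            # cannot happen on a consistent log: a child is born while its
            # template is alive, so the first ancestor born before the
            # window end was still alive after it
            raise KeyError(f"ancestor {cur} of {rid} not alive in window")
        if members is not None and cur not in members:
            continue
        out[cur] += 1
    return out


@dataclass
class RoleSpectrum:
    """Template/catalyst frequencies among ancestors vs the population."""

    template_type: int | None  # P=0 / Q=1, None if undifferentiated
    differentiated: bool
    ancestor_template_freq: float
    ancestor_catalyst_freq: float
    population_template_freq: float
    population_catalyst_freq: float


def ancestor_role_spectrum(
    ancestors: Counter,
    lineage: MolecularLineage,
    snapshot: Snapshot,
    k_max: float = 1.0,
) -> RoleSpectrum:
    """Frequency of template-type vs catalyst-type replicators among the
    window common ancestors and in the whole-population snapshot.

    Role assignment is type-based: the *template type* is the type with the
    smaller population-mean own-activity ``A_c`` in the snapshot, the
    *catalyst type* the other (after symmetry breaking, types and roles
    coincide).  If the own-activities show no catalytic asymmetry (ratio
    below 10 or the low side above ``0.05 k_max``) the world is flagged
    undifferentiated; frequencies are still reported for the lower-activity
    type.
    """
    if sum(ancestors.values()) == 0:
        raise ValueError("empty ancestor multiset")
    prof = snapshot.profile
    a = np.array([prof[:, 0:4].mean(), prof[:, 4:8].mean()])
    tmp_type = int(np.argmin(a))
    a_lo = max(float(a[tmp_type]), 0.0)
    a_hi = float(a[1 - tmp_type])
    eps = 0.05 * k_max
    differentiated = (a_lo < eps) and (a_hi > 10.0 * max(a_lo, eps / 10.0))

    n_anc = sum(ancestors.values())
    n_anc_tmp = sum(cnt for rid, cnt in ancestors.items()
                    if lineage.get_rtype(rid) == tmp_type)
    pop_tmp = float(np.mean(snapshot.rtype == tmp_type))
    return RoleSpectrum(
        template_type=tmp_type if differentiated else None,
        differentiated=differentiated,
        ancestor_template_freq=n_anc_tmp / n_anc,
        ancestor_catalyst_freq=1.0 - n_anc_tmp / n_anc,
        population_template_freq=pop_tmp,
        population_catalyst_freq=1.0 - pop_tmp,
    )
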