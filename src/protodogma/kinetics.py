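"""Within-protocell chemistry: complex formation, synthesis, mutation, decay.

The catalyst/template trade-off is realized mechanically: replication and
transcription require a transient complex between a catalyst and a template,
so a replicator sequestered as a catalyst in a step cannot simultaneously be
copied.  Complexes live for exactly one step: they form among the free
replicators of a cell, each either produces one replicator (consuming one
substrate unit) or produces nothing, and all dissociate before decay.

Per-step scheme within one cell (discrete time):

1. Free replicators are paired disjointly at random (``floor(n/2)`` pairs).
2. A sampled pair (X, Y) reacts with probability ``total / (4 k_max)`` where
   ``total`` is the sum of the four channel rates: X as catalyst producing P
   or Q from template Y (rates ``k[x][p][y]`` of X), and Y as catalyst
   producing P or Q from template X (rates ``k[y][p][x]`` of Y).  Negative
   heritable entries contribute rate zero.  The reacting channel is drawn
   proportionally to the four rates, fixing catalyst, template, and product
   type.  Reaction probability is thus proportional to
   ``sum_p k[x][p][y] + k[y][p][x]`` and an all-``k_max`` pair always reacts.
3. Complexes are visited in random order; while the cell still has
   substrate, each consumes one S and emits a replicator of its product type
   whose eight profile entries are copied from the *template*, each entry
   independently mutated with probability ``m`` by a Uniform(-delta, +delta)
   increment, reflected at the upper bound ``k_max`` (no lower bound).
4. Every replicator in the cell (newborns included) then independently
   decays with probability ``d``, returning one substrate unit each.

The hot path is compiled with numba; the compiled helpers draw from numba's
global RNG, seeded once per run via :func:`seed_kernel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "seed_kernel",
    "ChannelRates",
    "channel_rates",
    "mutate_profile",
    "form_complexes_cell",
    "reaction_substep",
]


@njit(cache=True)
def seed_kernel(seed):
    """Seed numba's global RNG used by all compiled chemistry helpers."""
    np.random.seed(seed)


@njit(cache=True)
def _eff(k):
    return k if k > 0.0 else 0.0


@njit(cache=True)
def _channel_rates(prof_a, ta, prof_b, tb):
    # entry index 4*c + 2*p + t; catalyst a of type ta, template b of type tb
    raP = _eff(prof_a[4 * ta + tb])
    raQ = _eff(prof_a[4 * ta + 2 + tb])
    rbP = _eff(prof_b[4 * tb + ta])
    rbQ = _eff(prof_b[4 * tb + 2 + ta])
    return raP, raQ, rbP, rbQ


@njit(cache=True)
def _shuffle(order, s0, nc):
    # Fisher-Yates on the segment order[s0 : s0+nc]
    for i in range(nc - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = order[s0 + i]
        order[s0 + i] = order[s0 + j]
        order[s0 + j] = tmp


@njit(cache=True)
def _form_complexes_cell(order, s0, nc, rtype, profile, k_max, cx_cat, cx_tmpl, cx_pt):
    """Pair consecutive members of the pre-shuffled segment; accept pairs.

    Returns the number of complexes written into the scratch arrays.
    """
    ncx = 0
    inv4k = 1.0 / (4.0 * k_max)
    for pidx in range(nc // 2):
        a = order[s0 + 2 * pidx]
        b = order[s0 + 2 * pidx + 1]
        raP, raQ, rbP, rbQ = _channel_rates(profile[a], rtype[a], profile[b], rtype[b])
        tot = raP + raQ + rbP + rbQ
        if tot <= 0.0:
            continue
        if np.random.random() < tot * inv4k:
            u = np.random.random() * tot
            if u < raP:
                cat, tmpl, pt = a, b, 0
            elif u < raP + raQ:
                cat, tmpl, pt = a, b, 1
            elif u < raP + raQ + rbP:
                cat, tmpl, pt = b, a, 0
            else:
                cat, tmpl, pt = b, a, 1
            cx_cat[ncx] = cat
            cx_tmpl[ncx] = tmpl
            cx_pt[ncx] = pt
            ncx += 1
    return ncx


@njit(cache=True)
def _mutate_copy(dst, src, m, delta_mut, k_max, mut_pre, mut_inc, n_mut, log_mut):
    """Copy the 8 template entries into dst with per-entry mutation."""
    for e in range(8):
        v = src[e]
        if m > 0.0 and np.random.random() < m:
            dk = (2.0 * np.random.random() - 1.0) * delta_mut
            nv = v + dk
            if nv > k_max:
                nv = 2.0 * k_max - nv
            if log_mut and n_mut < mut_pre.size:
                mut_pre[n_mut] = v
                mut_inc[n_mut] = dk
                n_mut += 1
            dst[e] = nv
        else:
            dst[e] = v
    return n_mut


@njit(cache=True)
def _synthesize_cell(
    cx_cat, cx_tmpl, cx_pt, ncx, sub_c, profile, m, delta_mut, k_max,
    c_prof, c_rtype, c_cell, c_tmpl, c_cat, ncl, cell_index,
    mut_pre, mut_inc, n_mut, log_mut,
):
    """Resolve a cell's complexes: substrate-limited births, then dissociation.

    Complexes beyond the substrate supply produce nothing.  Returns the
    updated (substrate, n_children, n_mutations) triple; child records are
    appended to the shared buffers starting at ``ncl``.
    """
    nb = ncx if ncx < sub_c else sub_c
    for k_i in range(nb):
        tmpl = cx_tmpl[k_i]
        n_mut = _mutate_copy(
            c_prof[ncl], profile[tmpl], m, delta_mut, k_max,
            mut_pre, mut_inc, n_mut, log_mut,
        )
        c_rtype[ncl] = cx_pt[k_i]
        c_cell[ncl] = cell_index
        c_tmpl[ncl] = tmpl
        c_cat[ncl] = cx_cat[k_i]
        ncl += 1
    return sub_c - nb, ncl, n_mut


@njit(cache=True)
def reaction_substep(cell_ix, rtype, profile, substrate, m, delta_mut, k_max, d, log_mut):
    """One reaction substep over the whole world (all cells).

    Mutates ``substrate`` in place (births consume, deaths release).
    Returns ``(dead, child_profile, child_rtype, child_cell, child_template,
    child_catalyst, child_dead, mut_pre, mut_inc, n_complexes)`` where the
    ``child_*`` arrays describe the newborns of this step (template/catalyst
    as indices into the input arrays) and ``dead`` flags decayed residents.
    """
    n = cell_ix.size
    n_cells = substrate.size

    # group replicator indices by cell (counting sort), then shuffle per cell
    counts = np.zeros(n_cells, np.int64)
    for i in range(n):
        counts[cell_ix[i]] += 1
    offsets = np.zeros(n_cells + 1, np.int64)
    for c in range(n_cells):
        offsets[c + 1] = offsets[c] + counts[c]
    order = np.empty(n, np.int64)
    fill = offsets[:n_cells].copy()
    for i in range(n):
        c = cell_ix[i]
        order[fill[c]] = i
        fill[c] += 1

    s_tot = 0
    for c in range(n_cells):
        s_tot += substrate[c]
    cap = s_tot if s_tot < n // 2 else n // 2
    if cap < 1:
        cap = 1
    c_prof = np.empty((cap, 8), np.float64)
    c_rtype = np.empty(cap, np.int8)
    c_cell = np.empty(cap, np.int32)
    c_tmpl = np.empty(cap, np.int64)
    c_cat = np.empty(cap, np.int64)
    c_dead = np.zeros(cap, np.bool_)
    dead = np.zeros(n, np.bool_)
    mut_cap = 8 * cap if log_mut else 1
    mut_pre = np.empty(mut_cap, np.float64)
    mut_inc = np.empty(mut_cap, np.float64)

    scr_cat = np.empty(n // 2 + 1, np.int64)
    scr_tmpl = np.empty(n // 2 + 1, np.int64)
    scr_pt = np.empty(n // 2 + 1, np.int8)

    n_mut = 0
    ncl = 0
    total_cx = 0
    for c in range(n_cells):
        s0 = offsets[c]
        nc_ = counts[c]
        if nc_ == 0:
            continue
        _shuffle(order, s0, nc_)
        ncx = _form_complexes_cell(
            order, s0, nc_, rtype, profile, k_max, scr_cat, scr_tmpl, scr_pt
        )
        total_cx += ncx
        child0 = ncl
        substrate[c], ncl, n_mut = _synthesize_cell(
            scr_cat, scr_tmpl, scr_pt, ncx, substrate[c], profile,
            m, delta_mut, k_max,
            c_prof, c_rtype, c_cell, c_tmpl, c_cat, ncl, c,
            mut_pre, mut_inc, n_mut, log_mut,
        )
        # decay: residents and this cell's newborns alike
        for ii in range(s0, s0 + nc_):
            if np.random.random() < d:
                dead[order[ii]] = True
                substrate[c] += 1
        for jj in range(child0, ncl):
            if np.random.random() < d:
                c_dead[jj] = True
                substrate[c] += 1

    return (
        dead,
        c_prof[:ncl].copy(),
        c_rtype[:ncl].copy(),
        c_cell[:ncl].copy(),
        c_tmpl[:ncl].copy(),
        c_cat[:ncl].copy(),
        c_dead[:ncl].copy(),
        mut_pre[:n_mut].copy(),
        mut_inc[:n_mut].copy(),
        total_cx,
    )


# -- python-level op surface -------------------------------------------------


@dataclass
class ChannelRates:
    """The four complex-formation channels of one replicator pair.

    ``rates`` is ordered (X catalyses P, X catalyses Q, Y catalyses P,
    Y catalyses Q) where X, Y are the two replicators as passed in.
    """

    rates: np.ndarray  # (4,) nonnegative
    total: float


def channel_rates(profile_x, tx: int, profile_y, ty: int, k_max: float) -> ChannelRates:
    """Rates of the four complexes a pair can form (negative entries -> 0)."""
    px = np.asarray(profile_x, dtype=np.float64)
    py = np.asarray(profile_y, dtype=np.float64)
    if np.any(px > k_max) or np.any(py > k_max):
        raise ValueError("profile entry exceeds k_max")
    r = np.array(_channel_rates(px, tx, py, ty), dtype=np.float64)
    return ChannelRates(rates=r, total=float(r.sum()))


def form_complexes_cell(rtype, profile, k_max: float, seed: int | None = None):
    """Run pairing + complex formation for one cell's replicators.

    Convenience wrapper over the compiled kernel for a single cell; returns
    ``(catalyst_index, template_index, product_type)`` arrays.  ``seed``
    (if given) seeds the kernel RNG first.
    """
    rtype = np.asarray(rtype, dtype=np.int8)
    profile = np.ascontiguousarray(profile, dtype=np.float64)
    n = rtype.size
    if seed is not None:
        seed_kernel(seed)
    order = np.arange(n, dtype=np.int64)
    _shuffle(order, 0, n)
    cat = np.empty(n // 2 + 1, np.int64)
    tmpl = np.empty(n // 2 + 1, np.int64)
    pt = np.empty(n // 2 + 1, np.int8)
    ncx = _form_complexes_cell(order, 0, n, rtype, profile, k_max, cat, tmpl, pt)
    return cat[:ncx].copy(), tmpl[:ncx].copy(), pt[:ncx].copy()


def mutate_profile(profile, m: float, delta_mut: float, k_max: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Mutate a profile: each entry independently, with probability ``m``,
    receives a Uniform(-delta_mut, +delta_mut) increment, reflected at
    ``k_max``; there is no lower bound.

    Reference (numpy Generator) path mirroring the compiled
    :func:`_mutate_copy`; both are covered by the same distributional tests.
    """
    prof = np.asarray(profile, dtype=np.float64)
    if np.any(prof > k_max):
        raise ValueError("profile entry exceeds k_max")
    out = prof.copy()
    hit = rng.random(out.shape) < m
    inc = rng.uniform(-delta_mut, delta_mut, size=out.shape)
    out[hit] += inc[hit]
    over = out > k_max
    out[over] = 2.0 * k_max - out[over]
    return out
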