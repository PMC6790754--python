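"""Statistics of snapshots and trajectories.

Implements the moment definitions used in the multilevel-selection analysis:
per-replicator trait projections, the within-cell / between-cell variance
decomposition and relatedness ``R = sigma2_cel / (sigma2_cel + sigma2_mol)``,
the Price-equation covariance decomposition, per-replicator reproductive
values from the 2x2 type-projection matrix, and the end-state phase
classifier (none / incomplete / threefold / ...).

One replicator is always one sample: all moments are replicator-weighted,
so cells enter with weights proportional to their size, and the law of total
variance ``sigma2_cel + sigma2_mol = total variance`` holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .world import P, Q, Snapshot, profile_index

__all__ = [
    "trait_projection",
    "mean_activities",
    "minority_frequency",
    "VarianceDecomposition",
    "variance_decomposition",
    "variance_decomposition_arrays",
    "PriceTerms",
    "price_decompose",
    "FitnessRecord",
    "empirical_fitness",
    "empirical_omega_bar",
    "reproductive_value",
    "PhaseStats",
    "phase_statistics",
    "classify_phase",
    "PHASE_LABELS",
]

PHASE_LABELS = ("none", "uncategorized", "incomplete", "threefold",
                "catalytic_informatic_only")


def trait_projection(snapshot: Snapshot, c: int) -> np.ndarray:
    """Per-replicator catalytic trait kappa^c: the mean of the replicator's
    four ``k[c][.][.]`` entries (raw heritable values, no clipping)."""
    return snapshot.profile[:, 4 * c: 4 * c + 4].mean(axis=1)


def mean_activities(snapshot: Snapshot) -> np.ndarray:
    """Unweighted population mean of each of the 8 profile entries."""
    if snapshot.n_replicators == 0:
        raise ValueError("empty snapshot: no replicators")
    return snapshot.profile.mean(axis=0)


def minority_frequency(snapshot: Snapshot, V: int) -> np.ndarray:
    """Per-cell frequency of the minority replicator type.

    Only cells with at least ``V/2`` particles (replicators + substrate) and
    at least one replicator are included; returns the collection of values
    ``min(#P, #Q) / (#P + #Q)`` for those cells.
    """
    uid_to_ix = {int(u): i for i, u in enumerate(snapshot.cells)}
    ix = np.array([uid_to_ix[int(u)] for u in snapshot.cell_uid], dtype=np.int64)
    n_cells = snapshot.n_cells
    counts = np.bincount(ix, minlength=n_cells)
    n_q = np.bincount(ix, weights=snapshot.rtype.astype(np.float64), minlength=n_cells)
    n_p = counts - n_q
    particles = counts + snapshot.substrate
    eligible = (particles >= V / 2) & (counts > 0)
    return np.minimum(n_p[eligible], n_q[eligible]) / counts[eligible]


# -- variance decomposition --------------------------------------------------


@dataclass
class VarianceDecomposition:
    sigma2_cel: float  # between-cell variance of the cell-mean trait
    sigma2_mol: float  # mean within-cell trait variance
    r: float  # relatedness; NaN when both variances vanish
    note: str | None = None


def variance_decomposition_arrays(traits: np.ndarray, cells: np.ndarray) -> VarianceDecomposition:
    """Decompose replicator-level trait variance into between-cell and
    within-cell components, every moment replicator-weighted."""
    traits = np.asarray(traits, dtype=np.float64)
    cells = np.asarray(cells)
    if traits.size < 2:
        raise ValueError("need at least 2 replicators")
    _, ix = np.unique(cells, return_inverse=True)
    n = traits.size
    counts = np.bincount(ix)
    cell_mean = np.bincount(ix, weights=traits) / counts
    per_rep_mean = cell_mean[ix]
    grand = traits.mean()
    s_cel = float(np.mean((per_rep_mean - grand) ** 2))
    s_mol = float(np.mean((traits - per_rep_mean) ** 2))
    tot = s_cel + s_mol
    if tot == 0.0:
        return VarianceDecomposition(0.0, 0.0, math.nan,
                                     note="all traits identical; R undefined")
    return VarianceDecomposition(s_cel, s_mol, s_cel / tot)


def variance_decomposition(snapshot: Snapshot, c: int) -> VarianceDecomposition:
    """Variance decomposition of the type-``c`` trait projection."""
    return variance_decomposition_arrays(trait_projection(snapshot, c), snapshot.cell_uid)


# -- Price decomposition -----------------------------------------------------


@dataclass
class PriceTerms:
    """lhs = mean fitness x expected trait change = between + within (exact)."""

    lhs: float
    between: float
    within: float


def price_decompose(traits: np.ndarray, fitness: np.ndarray, cells: np.ndarray) -> PriceTerms:
    """Price-equation decomposition of selection on a trait.

    ``<lambda> * Delta<kappa> = Cov_cells(<lambda>_i, <kappa>_i)
    + E_cells[Cov_within(lambda, kappa)]`` with all moments
    replicator-weighted.  Transmission is assumed faithful (the mutation
    model is unbiased), so no transmission-bias term appears.
    """
    k = np.asarray(traits, dtype=np.float64)
    lam = np.asarray(fitness, dtype=np.float64)
    cells = np.asarray(cells)
    if np.any(lam < 0):
        raise ValueError("fitness must be nonnegative")
    s_lam = lam.sum()
    if s_lam == 0:
        raise ValueError("total fitness is zero; offspring mean undefined")
    n = k.size
    mean_l = lam.mean()
    mean_k = k.mean()
    lhs = mean_l * (float(np.dot(lam, k)) / s_lam - mean_k)

    _, ix = np.unique(cells, return_inverse=True)
    counts = np.bincount(ix)
    lbar = np.bincount(ix, weights=lam) / counts
    kbar = np.bincount(ix, weights=k) / counts
    between = float(np.mean(lbar[ix] * kbar[ix]) - mean_l * mean_k)
    within_cell = (
        np.bincount(ix, weights=lam * k) / counts - lbar * kbar
    )
    within = float(np.dot(counts, within_cell) / n)
    return PriceTerms(lhs=lhs, between=between, within=within)


# -- reproductive value ------------------------------------------------------


@dataclass
class FitnessRecord:
    """Empirical per-template rates over a time window (diagnostic).

    ``omega[t]`` is the rate at which a template produced type-``t``
    offspring per step of the window; ``lam`` their sum.
    """

    rep_id: np.ndarray  # templates observed in the window
    omega_p: np.ndarray
    omega_q: np.ndarray

    @property
    def lam(self) -> np.ndarray:
        return self.omega_p + self.omega_q


def empirical_fitness(births: np.ndarray, window: tuple[int, int]) -> FitnessRecord:
    """Estimate per-template offspring rates from a birth log.

    ``births`` is the ``(n, 6)`` birth array (step, child, child_rtype,
    template, catalyst, cell); only events inside ``[t0, t1]`` count.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    sel = (births[:, 0] >= t0) & (births[:, 0] <= t1)
    ev = births[sel]
    if ev.shape[0] == 0:
        raise ValueError("no births in window")
    templates, ix = np.unique(ev[:, 3], return_inverse=True)
    length = float(t1 - t0)
    n_q = np.bincount(ix, weights=(ev[:, 2] == 1).astype(float))
    n_all = np.bincount(ix).astype(float)
    return FitnessRecord(rep_id=templates,
                         omega_p=(n_all - n_q) / length,
                         omega_q=n_q / length)


def empirical_omega_bar(births: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Normalized mean reproductive values ``(wP, wQ)`` from a birth log:
    ``w_t = <omega_t> / <lambda>`` over observed templates; sums to 1."""
    fr = empirical_fitness(births, window)
    lam = fr.lam.mean()
    return np.array([fr.omega_p.mean(), fr.omega_q.mean()]) / lam


def reproductive_value(omega_p: float, omega_q: float) -> tuple[float, np.ndarray]:
    """Fitness and reproductive values of a replicator.

    The per-step type projection matrix ``[[wP, wQ], [wP, wQ]]`` (both P and
    Q copies of a lineage produce P at rate wP and Q at rate wQ) has dominant
    eigenvalue ``lambda = wP + wQ``; its left eigenvector, normalized to sum
    1, gives Fisher's reproductive values ``u = (wP, wQ) / lambda``.  A role
    that is never copied (``wP = 0``) has zero reproductive value.
    """
    if omega_p < 0 or omega_q < 0:
        raise ValueError("rates must be nonnegative")
    lam = omega_p + omega_q
    if lam == 0:
        raise ValueError("both rates zero: fitness undefined")
    return lam, np.array([omega_p, omega_q]) / lam


# -- phase classification ----------------------------------------------------


@dataclass
class PhaseStats:
    """End-window statistics consumed by the phase classifier."""

    mean_k: np.ndarray  # (8,) window-averaged population means, storage order
    median_minority: float  # median per-cell minority frequency at window end
    window_length: int


def phase_statistics(trajectory, snapshot: Snapshot, window: tuple[int, int],
                     V: int) -> PhaseStats:
    """Build classifier inputs from a trajectory table and an end snapshot."""
    t0, t1 = window
    rows = trajectory[(trajectory["step"] >= t0) & (trajectory["step"] <= t1)]
    if len(rows) == 0:
        raise ValueError(f"no trajectory records in window [{t0}, {t1}]")
    mean_k = rows.iloc[:, 1:9].to_numpy(dtype=float).mean(axis=0)
    mino = minority_frequency(snapshot, V)
    med = float(np.median(mino)) if mino.size else math.nan
    return PhaseStats(mean_k=mean_k, median_minority=med, window_length=t1 - t0)


def classify_phase(stats: PhaseStats, k_max: float = 1.0,
                   min_window: int = 1000) -> str:
    """Classify the evolved end state.

    Declared thresholds (``eps = 0.05 * k_max``; ratio tests use a floor of
    ``eps / 10`` on the denominator and clip negative means to zero):

    - *catalytic* asymmetry: the lower of the two own-activity means
      ``A_c = mean of the four k^c entries`` is below ``eps`` and the higher
      exceeds 10x the lower;
    - *informatic* asymmetry: the catalyst type's reverse-transcription mean
      (producing the template type from a catalyst-type template) is below
      ``eps`` while its transcription mean (producing itself from a
      template-type template) exceeds 10x the reverse mean;
    - *numerical* asymmetry: median per-cell minority frequency below 0.4.

    Labels: ``none`` (neither catalytic nor informatic), ``incomplete``
    (catalytic only), ``threefold`` (catalytic + informatic + numerical),
    ``catalytic_informatic_only`` (catalytic + informatic, numerical
    absent), ``uncategorized`` (anything else).
    """
    if stats.window_length < min_window:
        raise ValueError(
            f"window of {stats.window_length} steps is shorter than the "
            f"configured minimum {min_window}"
        )
    mean_k = np.asarray(stats.mean_k, dtype=float)
    if np.any(np.isnan(mean_k)):
        raise ValueError("undefined mean activities (extinct window?)")
    eps = 0.05 * k_max
    floor = eps / 10.0

    a = np.array([mean_k[0:4].mean(), mean_k[4:8].mean()])
    cat_type = int(np.argmax(a))  # catalyst-type candidate
    tmp_type = 1 - cat_type
    a_lo = max(float(a[tmp_type]), 0.0)
    a_hi = float(a[cat_type])
    catalytic = (a_lo < eps) and (a_hi > 10.0 * max(a_lo, floor))

    trans = float(mean_k[profile_index(cat_type, cat_type, tmp_type)])
    rev = max(float(mean_k[profile_index(cat_type, tmp_type, cat_type)]), 0.0)
    informatic = (rev < eps) and (trans > 10.0 * max(rev, floor))

    numerical = (not math.isnan(stats.median_minority)) and stats.median_minority < 0.4

    if catalytic and informatic:
        return "threefold" if numerical else "catalytic_informatic_only"
    if catalytic:
        return "incomplete"
    if informatic:
        return "uncategorized"
    return "none"
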