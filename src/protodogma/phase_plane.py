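"""Deterministic mean-trait dynamics of the two replicator types.

The simplified model tracks only the mean catalytic activities
``(kP, kQ)`` in the box [0, 1]^2.  Per generation,

    dkP/dtau = wP * (beta * s2cel - gamma * s2mol) + wQ * beta * s2cel
    dkQ/dtau = wP * beta * s2cel + wQ * (beta * s2cel - gamma * s2mol)

where ``wc = exp(-s*kc) / (exp(-s*kP) + exp(-s*kQ))`` is the normalized
reproductive value of type ``c`` (the less catalytic type is replicated
more, so it carries more of the future population), ``s2cel``/``s2mol`` are
the between-cell and within-cell trait variances (parameters here), ``s``
the cost-benefit ratio, and by default ``beta = 1``, ``gamma = s``.

The box bound mimics the agent-based model's activity bounds: a flow
component is zeroed only when it points *outward* at a boundary
(outward-one-sided clamping), so a boundary state can still be left inward.

With the default coefficients the flow is a gradient system,

    (dkP, dkQ) = s2tot * grad[ R*B - (1-R)*C ],

with ``R = s2cel/s2tot`` (relatedness), ``B = kP + kQ`` and
``C = -log(exp(-s*kP) + exp(-s*kQ))``; the potential ``R*B - (1-R)*C`` is an
inclusive-fitness landscape.  The mechanism of symmetry breaking is visible
directly: for ``kP > kQ``, ``dkP - dkQ = s2mol * gamma * (wQ - wP) > 0``
whenever ``s2mol > 0`` — asymmetry is amplified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

__all__ = [
    "PhasePlaneParams",
    "Equilibrium",
    "omega_bar",
    "rhs",
    "potential",
    "potential_gradient_check",
    "find_equilibria",
    "basins",
]


@dataclass
class PhasePlaneParams:
    """Parameters of the mean-trait model.

    Defaults (``sigma2_cel = 1``, ``beta = 1``, ``gamma = s``, ``s = 1``)
    reproduce the standard phase-plane setting; only ``sigma2_mol`` is then
    swept to move between regimes.
    """

    sigma2_mol: float = 1.0
    sigma2_cel: float = 1.0
    s: float = 1.0
    beta: float = 1.0
    gamma: float | None = None  # defaults to s

    def __post_init__(self) -> None:
        if self.sigma2_mol < 0 or self.sigma2_cel < 0:
            raise ValueError("variances must be nonnegative")
        if self.s <= 0:
            raise ValueError("cost-benefit ratio s must be positive")
        if self.gamma is None:
            self.gamma = self.s


@dataclass
class Equilibrium:
    location: np.ndarray  # (2,)
    kind: str  # "symmetric" | "asymmetric"
    stability: str  # "stable" | "unstable" | "saddle"
    on_boundary: bool


def omega_bar(state, s: float) -> np.ndarray:
    """Normalized reproductive values (wP, wQ); sums to 1.

    ``wc = exp(-s*kc) / (exp(-s*kP) + exp(-s*kQ))``, evaluated in shifted
    form so it stays finite for any state the root-finder may visit.
    """
    kp, kq = state
    lo = min(kp, kq)
    ep = np.exp(-s * (kp - lo))
    eq = np.exp(-s * (kq - lo))
    return np.array([ep, eq]) / (ep + eq)


def _rhs_raw(state, p: PhasePlaneParams) -> np.ndarray:
    w = omega_bar(state, p.s)
    drive = p.beta * p.sigma2_cel - p.gamma * p.sigma2_mol
    return np.array([
        w[0] * drive + w[1] * p.beta * p.sigma2_cel,
        w[0] * p.beta * p.sigma2_cel + w[1] * drive,
    ])


def rhs(state, p: PhasePlaneParams, clamp: bool = True) -> np.ndarray:
    """Flow at ``state``; with ``clamp`` the outward component at a boundary
    is zeroed (inward flow at a boundary is kept)."""
    f = _rhs_raw(state, p)
    if clamp:
        kp, kq = state
        if (kp <= 0.0 and f[0] < 0.0) or (kp >= 1.0 and f[0] > 0.0):
            f = np.array([0.0, f[1]])
        if (kq <= 0.0 and f[1] < 0.0) or (kq >= 1.0 and f[1] > 0.0):
            f = np.array([f[0], 0.0])
    return f


def potential(state, p: PhasePlaneParams) -> float:
    """Inclusive-fitness potential ``R*B - (1-R)*C`` at ``state``."""
    kp, kq = state
    s2tot = p.sigma2_mol + p.sigma2_cel
    r = p.sigma2_cel / s2tot
    b = kp + kq
    c = -np.log(np.exp(-p.s * kp) + np.exp(-p.s * kq))
    return r * b - (1.0 - r) * c


def potential_gradient_check(states, p: PhasePlaneParams) -> float:
    """Max |s2tot * grad(potential) - rhs| over the given interior states.

    The gradient is evaluated in closed form
    (``s2tot * dPhi/dkc = s2cel - s2mol * s * wc``); equality with the flow
    holds identically for ``beta = 1, gamma = s``, so a deviation flags an
    implementation inconsistency between the two code paths.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    worst = 0.0
    for st in states:
        w = omega_bar(st, p.s)
        grad_flow = p.sigma2_cel - p.sigma2_mol * p.s * w
        dev = np.max(np.abs(grad_flow - rhs(st, p, clamp=False)))
        worst = max(worst, float(dev))
    return worst


# -- equilibria --------------------------------------------------------------

_TOL0 = 1e-12


def _classify_interior(state, p: PhasePlaneParams, h: float = 1e-7) -> str:
    jac = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        jac[:, j] = (_rhs_raw(state + e, p) - _rhs_raw(state - e, p)) / (2 * h)
    ev = np.linalg.eigvals(jac).real
    if np.all(ev < 0):
        return "stable"
    if np.all(ev > 0):
        return "unstable"
    return "saddle"


def _outward_sign(value: float, coord: float) -> float:
    """Positive if the flow component points outside the box at ``coord``."""
    return -value if coord == 0.0 else value


def find_equilibria(p: PhasePlaneParams, grid_n: int = 21,
                    dedup_tol: float = 1e-9) -> list[Equilibrium]:
    """Corner, edge and interior equilibria of the clamped flow.

    Corners are pinned (hence equilibria) when the raw flow points outward
    in both coordinates, and stable when it does so strictly.  Edge
    equilibria are roots of the tangential flow with the normal component
    pointing outward.  Interior equilibria come from multi-start
    root-finding on the raw flow over a deterministic ``grid_n x grid_n``
    grid (plus corners and edge midpoints as starts).
    """
    eqs: list[Equilibrium] = []

    def add(loc, stability, boundary):
        loc = np.asarray(loc, dtype=float)
        for e in eqs:
            if np.max(np.abs(e.location - loc)) < max(dedup_tol, 1e-9):
                return
        kind = "symmetric" if abs(loc[0] - loc[1]) < 1e-9 else "asymmetric"
        eqs.append(Equilibrium(loc, kind, stability, boundary))

    # corners: always fixed points of the reference box-clamped formulation;
    # "unstable" marks corners the outward-one-sided flow actually leaves
    for kp in (0.0, 1.0):
        for kq in (0.0, 1.0):
            f = _rhs_raw((kp, kq), p)
            op = _outward_sign(f[0], kp)
            oq = _outward_sign(f[1], kq)
            if op < -_TOL0 or oq < -_TOL0:  # inward flow: not pinned
                add((kp, kq), "unstable", True)
            elif op > _TOL0 and oq > _TOL0:
                add((kp, kq), "stable", True)
            else:
                # marginal pinning: probe slightly inside the box
                eps = 1e-6
                probe = (kp + (eps if kp == 0.0 else -eps),
                         kq + (eps if kq == 0.0 else -eps))
                fpr = _rhs_raw(probe, p)
                inward_p = _outward_sign(fpr[0], kp) < 0
                inward_q = _outward_sign(fpr[1], kq) < 0
                add((kp, kq), "saddle" if (inward_p or inward_q) else "stable", True)

    # edges: tangential roots with outward normal flow
    grid = np.linspace(1e-6, 1 - 1e-6, 201)
    for fixed_axis, fixed_val in ((1, 0.0), (1, 1.0), (0, 0.0), (0, 1.0)):
        free_axis = 1 - fixed_axis

        def tang(x):
            st = np.empty(2)
            st[fixed_axis] = fixed_val
            st[free_axis] = x
            return _rhs_raw(st, p)[free_axis]

        vals = np.array([tang(x) for x in grid])
        for i in range(len(grid) - 1):
            if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
                x0 = grid[i] if vals[i] == 0.0 else brentq(
                    tang, grid[i], grid[i + 1], xtol=1e-14)
                st = np.empty(2)
                st[fixed_axis] = fixed_val
                st[free_axis] = x0
                f = _rhs_raw(st, p)
                normal_out = _outward_sign(f[fixed_axis], fixed_val)
                if normal_out < -_TOL0:
                    continue  # not pinned: no clamped equilibrium here
                h = 1e-7
                slope = (tang(x0 + h) - tang(x0 - h)) / (2 * h)
                tang_stable = slope < 0
                norm_stable = normal_out > _TOL0
                if tang_stable and norm_stable:
                    stab = "stable"
                elif tang_stable or norm_stable:
                    stab = "saddle"
                else:
                    stab = "unstable"
                add(st, stab, True)

    # interior: multi-start root finding on the raw flow
    starts = [np.array([a, b]) for a in np.linspace(0, 1, grid_n)
              for b in np.linspace(0, 1, grid_n)]
    starts += [np.array([0.5, 0.0]), np.array([0.5, 1.0]),
               np.array([0.0, 0.5]), np.array([1.0, 0.5])]
    margin = 1e-7
    for st0 in starts:
        sol = root(lambda x: _rhs_raw(x, p), st0, method="hybr",
                   options={"xtol": 1e-13})
        if not sol.success:
            continue
        x = sol.x
        if not (margin < x[0] < 1 - margin and margin < x[1] < 1 - margin):
            continue
        if np.max(np.abs(_rhs_raw(x, p))) > 1e-10:
            continue
        add(x, _classify_interior(x, p), False)

    return eqs


# -- basins of attraction ----------------------------------------------------


def basins(p: PhasePlaneParams, resolution: int = 21, dtau: float = 0.15,
           horizon: int = 5000, tol: float = 1e-6):
    """Basin label for every point of a regular grid over the box.

    Integrates the clamped flow with explicit Euler steps of ``dtau``
    (states clipped to the box, which realizes the clamping) until the
    trajectory comes within ``tol`` of a stable equilibrium or the horizon
    is hit.  Returns ``(labels, stable_equilibria, grid_axis)`` where
    ``labels[i, j]`` indexes the attractor reached from
    ``(axis[i], axis[j])`` and -1 marks undetermined points.
    """
    eqs = [e for e in find_equilibria(p) if e.stability == "stable"]
    attractors = np.array([e.location for e in eqs]) if eqs else np.empty((0, 2))
    axis = np.linspace(0.0, 1.0, resolution)
    labels = np.full((resolution, resolution), -1, dtype=np.int64)
    for i, kp in enumerate(axis):
        for j, kq in enumerate(axis):
            x = np.array([kp, kq])
            lab = -1
            for _ in range(horizon):
                if attractors.size:
                    dist = np.max(np.abs(attractors - x), axis=1)
                    kbest = int(np.argmin(dist))
                    if dist[kbest] < tol:
                        lab = kbest
                        break
                x = np.clip(x + dtau * rhs(x, p, clamp=True), 0.0, 1.0)
            labels[i, j] = lab
    return labels, eqs, axis
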