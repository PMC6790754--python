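# Methods

## The model

`protodogma` simulates a population of protocells, each containing a
population of self-replicating catalytic molecules of two types, P and Q,
plus substrate particles S.  The total particle number `n_tot` (replicators
of both types plus free substrate) is exactly conserved: every birth
consumes one S, every decay releases one S.

Each replicator carries eight heritable catalytic activities
`k[c][p][t]` with `c, p, t ∈ {P, Q}`: the rate constants with which a
type-`c` catalyst forms a complex that produces a type-`p` replicator from
a type-`t` template.  Four entries (`c` = the carrier's own type) are the
carrier's activities; the other four are the activities of its transcripts.
Values start at `k_max` for every replicator, so the two types are
initially indistinguishable (a symmetric initial condition), and evolve by
unbiased mutation: at each birth, each entry independently receives, with
probability `m`, a Uniform(−δ, +δ) increment, reflected at `k_max` and
unbounded below (entries below zero contribute zero rate).

The central mechanical assumption is a catalyst/template trade-off:
replication and transcription require a transient catalyst–template
complex, so time spent catalysing is time not spent being copied.  Serving
as catalyst is favoured *between* cells (it accelerates the cell's
substrate conversion) and disfavoured *within* cells (it forfeits copying
opportunities) — conflicting multilevel selection.  The question the model
answers is whether this conflict spontaneously differentiates P and Q into
a non-catalytic "genome" (template) type and a catalytic "enzyme" type
with one-way information flow between them.

## Scheduler

One time step is three substeps, in fixed order:

1. **Reaction**, per cell:
   - free replicators are paired disjointly at random, `⌊n/2⌋` pairs;
   - a pair (X, Y) reacts with probability `total / (4 k_max)` where
     `total` is the sum of the four channel rates (X catalyses P or Q from
     template Y; Y catalyses P or Q from template X); the channel is drawn
     proportionally to the four rates.  Reaction probability is therefore
     proportional to `Σ_p k[x][p][y] + k[y][p][x]`, and an all-`k_max` pair
     always reacts;
   - complexes are visited in random order; while the cell holds
     substrate, each consumes one S and emits a replicator whose profile is
     copied (with mutation) from the *template* — the template cannot
     influence whether it is replicated or transcribed, only the catalyst's
     rates decide;
   - all complexes dissociate; every replicator in the cell, newborns
     included, then decays with probability `d`, releasing one S each.
2. **Diffusion**: all substrate in the world is pooled and re-distributed
   multinomially over cells with probabilities proportional to replicator
   counts (substrate diffuses fast; replicators not at all).  A world with
   no replicators left keeps its substrate in place.
3. **Division**: every cell with more than `V` particles splits, each
   particle independently assigned to either daughter; both daughters get
   fresh identities (the parent id is retired to the division log).  Cells
   with zero particles are removed.

Complexes live exactly one step.  This is the simplest scheme that still
sequesters catalysts, which is all the trade-off requires; within-step
persistence would add a free parameter with no observable of interest
attached to it.

The unit of time is fixed by decay: one replicator decays with probability
`d` per step, so mean lifetime is `1/d` steps and one generation is about
`1/d` steps.

**Reproducibility.** A run uses two deterministic RNG streams, both derived
from the run seed: numba's global RNG drives all within-cell chemistry (the
compiled kernel), a `numpy.random.Generator` drives the scheduler
(diffusion, division).  Identical seed and parameters give bit-identical
outputs.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `V` | division threshold (particles) | 100 | the main size control; larger `V` raises within-cell relative to between-cell variance |
| `m` | mutation probability per entry per birth | 0.01 | applied independently to each of the 8 entries |
| `d` | decay probability per step | 0.02 | defines the time unit; mean lifetime 50 steps |
| `delta_mut` | half-width of the uniform mutation increment | 0.05 | `k` units |
| `k_max` | upper (reflecting) bound on activities | 1.0 | no lower bound; negative values are catalytically inert |
| `n_tot` | conserved particle total | `50·V` | keeps the protocell count independent of `V` |
| `init_cells` | founding protocells | 50 | each founded at exactly `V` particles, so no division at step 0 |

At initialization, types alternate P, Q within each cell: the global P:Q
split is stated as equal, and per-cell alternation is the deterministic
assignment that achieves it to within parity at both levels.

## Demography under these rules

With the above rules, a cell's particle count is a critical random walk:
its expected substrate influx (proportional to its replicator count)
exactly balances its expected decay loss, and the per-step variance of the
count is proportional to the count itself.  The stationary cell-size
density is then uniform below `V/2` and falls off as `(V−n)/n` above,
giving a mean size near `0.36 V` and hence a quasi-stationary count near
`1.4 · n_tot/V` (≈ 130–140 cells at the defaults) rather than the
`n_tot/(V/2) = 100` that the naive picture of cells cycling between `V/2`
and `V` suggests.  The acceptance script reports the measured count; the
decay-rate and mutation-width recoveries (geometric-MLE hazard, uniform
half-width) are exact to well within a percent.

Lifetime convention: a replicator born during step `b` faces its first
decay trial in that same step; founders face theirs in step 1.  A death in
step `t` therefore completes `t − b + 1` trials (founders: `t`), a
geometric variable with per-trial hazard `d`.  The geometric MLE is
`deaths / total trials`; on short runs the completed-lifetime estimator is
censoring-biased (long lives are preferentially unfinished), so tests
either run long enough that the bias is negligible or add the censored
exposure of survivors.

## A property of the chosen reaction scheme

Because every pair reacts with probability `total/(4 k_max)`, a cell's
complex formation outpaces its per-step substrate allocation (about `d·n`
at stationarity) once mean activities exceed roughly `2d ≈ 0.04`.  Above
that level conversion is substrate-limited and between-cell selection is
only weakly sensitive to activity — the remaining benefit comes from rare
fluctuation-driven conversion shortfalls (measured as a small but
significantly positive growth advantage of an all-1.0 cell over an
all-0.2 cell, versus near-total substrate capture against an all-0.02
cell).  Within-cell selection (the copying disadvantage of acting as
catalyst in a complex) remains active at all levels.  The consequence,
observed in long runs, is that mean activities drift downward from the
symmetric `k_max` start toward the conversion-limit region, and the weak
high-activity cellular benefit cannot maintain a highly catalytic type.
The per-capita birth rate is monotonically *nondecreasing* in a shared
activity level (rising, then substrate-limited).

## Observables

All moments count one replicator as one sample (cells weighted by size).
For type `c`, the per-replicator trait is `κ^c` = mean of the four raw
`k[c]` entries (no clipping).  `sigma2_cel` is the variance over
replicators of their cell-mean trait; `sigma2_mol` the mean within-cell
variance; relatedness `R = sigma2_cel / (sigma2_cel + sigma2_mol)`.  The
law of total variance holds exactly by construction.

The Price decomposition splits selection on a trait into a between-cell
covariance (cell-mean fitness vs cell-mean trait) and the mean within-cell
covariance; `lhs = between + within` is an algebraic identity and is
asserted to 1e−12.  Transmission is faithful (mutation unbiased), so no
transmission term is included.

Per-replicator fitness uses the 2×2 type-projection matrix
`[[ωP, ωQ], [ωP, ωQ]]`: dominant eigenvalue `λ = ωP + ωQ`, reproductive
values `u ∝ (ωP, ωQ)` (left eigenvector, normalized to sum 1).  A role
that is never copied has reproductive value zero.

**Phase classifier.**  The end state of a run is labelled from
window-averaged statistics with explicit, declared thresholds
(`eps = 0.05 k_max`, ratio floor `eps/10`, negative means clipped to 0):

- *catalytic* asymmetry: the smaller own-activity mean `A_c` below `eps`
  and the larger exceeding 10× the smaller;
- *informatic* asymmetry: the catalyst type's reverse-transcription mean
  below `eps` with its transcription mean 10× larger;
- *numerical* asymmetry: median per-cell minority frequency below 0.4
  (cells with at least `V/2` particles).

Labels: `none`, `incomplete` (catalytic only), `threefold` (all three),
`catalytic_informatic_only`, `uncategorized`.  Windows shorter than a
configured minimum are refused rather than classified.

**Ancestor role spectrum.**  Ancestor tracking is two-stage: common
ancestors of all surviving protocells are found on the cell division tree;
template lineages of the final population are then traced back to the
unique lineage member alive in the analysis window, restricted to
replicators contained in the common-ancestor cells.  Roles are assigned by
type (template type = the type with the smaller mean own-activity), which
coincides with instantaneous roles once symmetry is broken; in an
undifferentiated world the spectrum is flagged as such.

## Phase-plane model

The deterministic mean-trait model evolves `(kP, kQ)` in `[0,1]²`:

    dkc/dτ = ω̄c (β σ²cel − γ σ²mol) + ω̄c' β σ²cel,
    ω̄c = exp(−s·kc) / (exp(−s·kP) + exp(−s·kQ)),

with defaults β = 1, γ = s, σ²cel = 1, s = 1.  With those coefficients the
flow is the gradient system `σ²tot ∇[R·B − (1−R)·C]` with
`R = σ²cel/σ²tot`, `B = kP + kQ`, `C = −log(e^{−s·kP} + e^{−s·kQ})`; the
implementation verifies the two code paths against each other (and a test
adds a finite-difference oracle).  The amplification mechanism is explicit:
`dkP − dkQ = γ σ²mol (ω̄Q − ω̄P) > 0` whenever `kP > kQ`, so any asymmetry
grows while within-cell variance is positive.

**Boundary handling.**  A flow component is zeroed only when it points
*outward* at a boundary (outward-one-sided clamping).  The alternative
literal reading — boundaries always absorbing — would make the symmetric
corner (1,1) unconditionally stable, contradicting its loss of stability
at large `σ²mol`; the one-sided rule is the only reading consistent with
that instability.  Corners are nevertheless always reported as equilibria
(they are fixed points of the absorbing formulation), with `unstable`
marking corners the one-sided flow leaves.

Closed-form corner conditions (σ²cel = 1, s = 1) used as oracles:
`(1,1)` pinned-stable iff `σ²mol ≤ 2`; `(1,0)` pinned-stable iff
`1 + e^{−1} ≤ σ²mol ≤ 1 + e`.

Equilibria are found from a deterministic multi-start grid (21×21 plus
corners and edge midpoints): corners by flow signs, edges by bracketed
root-finding on the tangential component with an outward normal, interior
points by Newton-type root-finding, deduplicated at 1e−9; interior
stability via the numerical Jacobian, boundary stability via one-sided
flow signs.  Basins integrate the clamped flow with explicit Euler steps
(Δτ = 0.15, states clipped to the box, which realizes the clamping and
lets trajectories reach corner attractors exactly); non-convergent points
are labelled undetermined rather than guessed.

## Synthetic snapshot fixtures

The fixture generator builds populations with *exactly* prescribed
`sigma2_cel` and `sigma2_mol` by two-point constructions at both levels
(half the cells at mean ± √sigma2_cel; within each cell, half the members
at cell-mean ± √sigma2_mol), with all eight entries equal to the trait.
It emulates only what the moment estimators consume — cell structure and
trait dispersion — and none of the dynamics: no substrate, no type-trait
correlation, no mutation history.  Passing parameter-recovery tests on
fixtures therefore validates the estimators' arithmetic, not the
simulator; simulator behaviour is tested on real (short) runs.

## Scaled probe of symmetry breaking

Full-scale runs (V = 10⁴, 5×10⁷ steps) are cluster-scale and out of scope.
The suite probes the qualitative contrast at a reduced setting chosen once
for budget: a high-variance regime (V = 200 with the elevated mutation
setting m = 0.05, δ = 0.1, 4×10⁴ steps) against a high-relatedness control
(V = 100, m = 0.001), plus an ancestor-spectrum check on a
genealogy-logged continuation of the high-variance run.  The control
behaves as theory predicts (no differentiation, activities stay high).
The high-variance regime, however, does *not* reach a stable
catalytic/informatic differentiation under the one-step maximally reactive
scheme — activities collapse toward the conversion-limit region without a
persistent type asymmetry (see the previous section for the mechanism),
and the corresponding tests record that discrepancy rather than papering
over it.  The phase-plane model, whose variances are free parameters,
carries the full symmetry-breaking analysis independently of the
agent-based scheme.

## Known limitations

- The reaction scheme is a declared reconstruction (the source describes
  it only by reference); pair sampling without replacement and one-step
  complexes are choices, isolated in a single kernel function.
- One-step complexes make catalyst sequestration nearly costless in *time*
  (one step of a ~50-step lifetime); the molecular-level cost acts instead
  through channel choice within a reacting pair.  Combined with the
  weakness of between-cell selection at high activities (see above), the
  agent-based model under this scheme does not sustain a highly catalytic
  differentiated type; a scheme with finite synthesis duration (persistent
  complexes) would make the time trade-off explicit but is not in scope.
- The quasi-stationary protocell count under these rules is ≈ 1.3–1.4
  · n_tot/V, not n_tot/(V/2); see the demography section.
- Numerical symmetry breaking (minority templates) requires product-type
  dependence of activities and long horizons; at desk scale the classifier
  may report `catalytic_informatic_only` where the full-scale system would
  show `threefold`.
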