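# protodogma

Agent-based simulation and analysis of how a genome/enzyme division of
labour — the functional core of the central dogma — can emerge from
conflicting multilevel selection in protocells.

## The problem

Origin-of-life scenarios start from a single kind of molecule that both
stores information and catalyses reactions.  How do such replicators
differentiate into non-catalytic *templates* (genomes) and catalytic,
informatically dead-ended *enzymes*?  `protodogma` models a population of
protocells, each holding replicators of two types (P and Q) that compete
for a conserved substrate S.  Every replicator carries eight heritable
catalytic activities `k[c][p][t]` — the rate at which a type-`c` catalyst
produces a type-`p` copy from a type-`t` template.  Copying requires a
transient catalyst–template complex, so acting as a catalyst forfeits
copying opportunities: catalysis is favoured by selection *between* cells
(faster substrate conversion) and disfavoured *within* cells.  The package
simulates this two-level process and provides the analytical machinery to
explain its outcome:

- **Price decomposition** of selection into between-cell and within-cell
  covariance terms (an exact identity, asserted to 1e−12);
- **variance partitioning** `sigma2_cel` / `sigma2_mol` and relatedness
  `R = sigma2_cel / (sigma2_cel + sigma2_mol)`;
- **Fisher reproductive values** from the 2×2 type-projection matrix
  `[[wP, wQ], [wP, wQ]]` (`lambda = wP + wQ`, `u ∝ (wP, wQ)`);
- **two-level ancestor tracking** (common-ancestor protocells, then
  template lineages) and the template/catalyst ancestor role spectrum;
- a **deterministic phase-plane model** of the mean traits
  `(kP, kQ)`, `dkc/dτ = ω̄c(β σ²cel − γ σ²mol) + ω̄c' β σ²cel` with
  `ω̄c = e^{−s·kc}/(e^{−s·kP}+e^{−s·kQ})`, equivalent (for β=1, γ=s) to
  gradient ascent on the inclusive-fitness potential `R·B − (1−R)·C`.

The signature phenomenon is spontaneous symmetry breaking: when
within-cell variance is large relative to between-cell variance (large
cells, high mutation rates), one type loses catalytic activity and becomes
a pure template while the other becomes a pure catalyst, with information
flowing one way — templates are transcribed into catalysts but not back —
and the common ancestors of the population being almost exclusively
templates ("catalysts have zero reproductive value").

## Worked example

```python
from protodogma import Params, run, variance_decomposition

params = Params(V=100, m=0.01, t_max=2000, record_every=500, seed=1)
result = run(params)
row = result.trajectory.iloc[-1]
print(f"cells={int(row.cell_count)}  freq_S={row.freq_S:.3f}  "
      f"mean kP block={row.iloc[1:5].mean():.3f}")

snap = result.final_snapshot
vd = variance_decomposition(snap, c=0)
print(f"sigma2_cel={vd.sigma2_cel:.2e}  sigma2_mol={vd.sigma2_mol:.2e}  "
      f"R={vd.r:.3f}")
```

prints (exactly, for this seed):

```
cells=131  freq_S=0.022  mean kP block=0.992
sigma2_cel=2.54e-05  sigma2_mol=3.00e-05  R=0.459
```

Reading: after 2000 steps (40 generations at `d = 0.02`) the 50 founding
cells have grown to a quasi-stationary count above 100; about 2% of the
conserved particles are free substrate; mean activities have drifted just
below the initial `k_max = 1`; and already over half of the trait variance
of the P-activity projection lies *within* cells — the lever that
molecular-level selection acts on (relatedness `R ≈ 0.46`).

The same machinery is scriptable from the shell:

```sh
protodogma simulate --config cfg.yaml --out out/
protodogma phaseplane --sigma2-mol 2.5 --out pp/
protodogma analyze --snapshots out/snapshots.jsonl \
    --trajectory out/trajectory.tsv --window 10000 20000 --v 100 --out stats
```

`phaseplane` writes the equilibria of the mean-trait model; at
`sigma2_mol = 2.5` (with `sigma2_cel = 1`) the symmetric state `(1,1)` is
unstable and the asymmetric corners `(1,0)`/`(0,1)` — one type catalytic,
the other a pure template — are the attractors.

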