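# rnaiquant

Quantitative models of gene-specific RNA interference (RNAi) in
*C. elegans* somatic cells.

Feeding worms double-stranded RNA silences matching genes, but different
target genes have different genetic requirements: silencing of the
hypodermal gene *bli-1* needs each of the regulators MUT-16, RDE-10, and
NRDE-3, while the muscle gene *unc-22* is silenced as long as any two of
them are present. This package implements, as tested reusable code, the
quantitative arguments that explain such target-specific outcomes
without invoking target-specific pathways:

1. **Intersecting network with gene-specific thresholds**
   (`rnaiquant.network`). After 1° siRNA processing, silencing signal
   flows through four paths — Nm (MUT-16→NRDE-3), Nr (RDE-10→NRDE-3),
   Om (MUT-16→other Argonautes), Or (RDE-10→other Argonautes) — and a
   target is silenced when the summed contribution of its intact paths
   reaches the target's threshold (T_unc-22 as the unit gauge,
   T_bli-1 = sampled ratio). `NetworkModel.fit(n, seed)` draws path
   contributions uniformly from [0, 2] and threshold ratios from
   [0, 100], and culls the sets consistent with the observed
   genotype–phenotype table (wild type silences both targets, singles
   only *unc-22*, doubles neither).
2. **Sequential equilibrium model** (`rnaiquant.equilibrium`). Dicing,
   target recognition, 2° siRNA amplification, and mRNA/pre-mRNA
   depletion are evaluated as sequential equilibria with irreversible
   consumption; sampling classifies parameter sets that knock a gene
   down ( [m]ᵢ < [m] ) while leaving it expressed ( [m]ᵢ > 0, [p]ᵢ > 0 ).
3. **Dynamic ODE model** (`rnaiquant.dynamics`). Six coupled rate
   equations for dsRNA, 1° siRNA, pUG RNA, 2° siRNA, pre-mRNA, and mRNA,
   integrated with 4th-order Runge–Kutta under a non-negativity bounding
   rule, with knockdown metrics (τ_kd: time to fall below 10 % of
   initial mRNA; t_kd: time spent below), parameter sweeps, a
   transcription-doubling experiment, and a turnover experiment
   comparing genes with equal steady-state mRNA but different turnover.

Two analysis utilities complete the workflow used to generate and score
the underlying data:

- `rnaiquant.stats` — Wilson score intervals with continuity correction
  for fraction-silenced counts, and continuity-corrected two-proportion
  comparisons (α = 0.05).
- `rnaiquant.complementation` — in silico complementation: filter
  HIGH/MODERATE snpEff variants, discard variants shared between
  strains, and group strains carrying distinct mutations in the same
  gene.

`rnaiquant.synthetic` generates seeded fixtures (binomial phenotype
counts from a ground-truth network, per-strain annotated VCFs with
planted complementation groups, parameter grids) so every stage runs
with no downloads.

## Worked example

```python
from rnaiquant import NetworkModel

results = NetworkModel().fit(n=100_000, seed=1)
print(results.summary())
```

```
Intersecting-network constraint sampling
----------------------------------------
sampled parameter sets : 100000
accepted               : 134 (0.134%)
seed                   : 1
weight range           : (0.0, 2.0)
threshold ratio range  : (0.0, 100.0)
t_unc gauge            : 1.0
max accepted ratio     : 4.926
MUT-16 fraction        : 0.504 (mean), [0.317, 0.691]
NRDE-3 fraction        : 0.633 (mean), [0.361, 0.761]
```

Of 100,000 random parameter sets, 134 (≈0.13 %) are consistent with all
fourteen observed silencing outcomes. Across every accepted set the
*bli-1* threshold stays below ~5× the *unc-22* threshold even though
ratios up to 100 were allowed, and neither the MUT-16- nor the
NRDE-3-requiring share of the silencing signal takes extreme values —
the observed all-or-none genetics is compatible with a single network of
quantitatively contributing regulators.

Kinetics of one knockdown:

```python
from rnaiquant import DynamicsModel

traj = DynamicsModel().simulate()       # reference parameters, dose at t=0
m = traj.knockdown_metrics()
print(m.tau_kd, m.t_kd, round(m.m_min, 4))
# 3.41 131.74 0.0011
```

mRNA falls below 10 % of its initial level at t ≈ 3.4 a.u., stays below
for ≈ 132 a.u., and recovers to baseline as the silencing intermediates
turn over. The command line mirrors the library:
`rnaiquant network sample --n 100000 --seed 1 --out out/`,
`rnaiquant ode run --out out/`, `rnaiquant eq sample`,
`rnaiquant stats score --in counts.tsv`, `rnaiquant comp run --vcf-dir vcfs/`.

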