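# Methods

This note records the models implemented in `rnaiquant`, the defaults
and why they were chosen, the numerical conventions, and the limits of
what the synthetic-data tests demonstrate.

## Intersecting-network constraint simulation

**Model.** Somatic RNAi signal branches after 1° siRNA processing into
four paths distinguished by the amplification factor (MUT-16 or RDE-10)
and the downstream Argonaute (NRDE-3 or any other Argonaute): Nm, Nr,
Om, Or, with nonnegative contributions `nm, nr, om, or_`. A genotype's
silencing signal for a target is the sum over paths whose two required
regulators are functional; the target is silenced when the signal
reaches its gene-specific threshold. Two targets are modeled: the
sensitive *unc-22* (threshold `T_unc`) and the demanding *bli-1*
(threshold `T_bli`).

**Gauge.** Only the ratio `T_bli/T_unc` is identifiable: scaling all
four contributions and both thresholds by the same factor changes no
accept/reject decision. `T_unc` is therefore fixed at 1 and the ratio is
the sampled quantity. The gauge value is exposed in configuration.

**Tie-break.** Signal exactly equal to the threshold counts as silenced
(`>=`). Under continuous uniform sampling the boundary has probability
zero, so this convention cannot change acceptance counts; it is
documented for the discrete grid enumerator, where it does matter.

**Constraint table.** The fourteen constraints are the seven genotypes
(wild type; *mut-16(−)*; *rde-10(−)*; *nrde-3(−)*; the three pairwise
doubles) × two targets: wild type silences both, each single mutant
silences *unc-22* only, each double mutant silences neither. The
wild-type *unc-22* row is implied by the others but kept for
auditability. Graded (weak-dose) responses and other target genes are
intentionally not constraints.

**Sampling.** `n` independent tuples, each with the four contributions ~
U[0, 2] and the ratio ~ U[0, 100], one `numpy` Generator seeded at the
top level. The default-table accept/reject is vectorized; a scalar
re-implementation (`satisfies_constraints`) is used for custom tables
and serves as the oracle in tests (grid enumeration must agree
point-for-point). An analytic consequence worth noting: acceptance
requires `ratio <= nm+nr+om+or_` with `om, or_ < 1`, so the maximum
accepted ratio is strictly below 6; at n = 100,000 the observed maximum
is typically ≈ 5, and the acceptance fraction is ≈ 0.13 %.

## Sequential equilibrium model

All reactions are assumed to have reached equilibrium, with four
additional assumptions: (1) 1° siRNAs, then pUG RNAs, then 2° siRNAs
arise strictly in sequence; (2) no 3° siRNAs; (3) no recycling of
full-length mRNA or pre-mRNA after small RNA binding (consumption is
irreversible, residuals clamp at zero); (4) no other turnover on this
timescale. The stage algebra is:

```
pri = e_dice * dose * l_ds/22          # dicing
ug  = min(e_pri * pri, m)              # recognition; one pUG per cleaved mRNA
sec = amp * ug                         # RdRP amplification
m_i = max(m - ug - e_sec_m * sec, 0)   # mRNA depletion
p_i = max(p - e_sec_p * sec, 0)        # pre-mRNA depletion
```

A parameter set is classified as "knocked down and viable" when
`0 < m_i < m` and `p_i > 0`. Defaults: pools m = 100, p = 50 (matching
the dynamic model's baseline), trigger length 100 nt; sampling ranges
dose ∈ [0, 10], efficiencies e_dice, e_pri, e_sec_m, e_sec_p ∈ [0, 1],
amplification ∈ [0, 100] (2° siRNAs are the abundant species, so up to
two orders of magnitude of gain per template). These ranges are this
package's own choices; under them roughly half of all draws classify
positive, because moderate amplification is often survivable. The
scientific claims the model supports are range-independent and are what
the tests assert: residuals never exceed the initial pools, accepted
sets span heterogeneous residual levels, silencing can change the
pre-mRNA:mRNA ratio, and residual mRNA is monotone non-increasing in the
recognition efficiency. The solver is guarded by a deliberately naive
straight-line re-derivation in the test suite (dual-implementation
oracle).

## Dynamic ODE model

Six species: dsRNA `ds`, 1° siRNA `pri`, pUG RNA `ug`, 2° siRNA `sec`,
pre-mRNA `p`, mRNA `m`. The rate equations are listed in the module
docstring (`rnaiquant/dynamics.py`); their structure encodes: trigger
consumption by dicing; 1° siRNA production at `k1*ds*(l_ds/22)` (one
22-nt siRNA per 22 nt of trigger), loss by target binding `k2*pri*m` and
turnover; pUG production from recognized mRNA (`k3*pri*m`); 2° siRNA
production from pUG templates (`k4*l_m*ug` — templates are not consumed);
2° siRNA loss by binding mRNA (`k5`) and pre-mRNA (`k6`);
transcription `k9`, export/splicing `k7`, and transcriptional repression
by pre-mRNA-bound 2° siRNA (`k8*sec*p`). Every binding term removes the
bound partners symmetrically, so with a single binding constant active
and all turnovers zero the pairwise differences (pri−m, sec−m, sec−p)
are conserved — asserted in tests as mass-balance checks.

**Baseline.** Without silencing species, `p* = k9/(k7+t_p)` and
`m* = k7 p*/t_m` (= 50 and 100 for the reference parameters). The
simulator verifies this is a fixed point to ~1e-9 relative drift.

**Integrator.** Classical RK4 with fixed step (default dt = 0.01 a.u.,
horizon t_end = 500 a.u.). Non-negativity: after composing the full RK4
increment `dx`, each species keeps `x+dx` only if positive and is set to
exactly 0 otherwise. Bounding the composed update (rather than inside
RK4 stages) preserves the 4th-order error structure away from zero;
stage states are projected to nonnegative values before evaluating the
right-hand side so the equations are never fed negative concentrations.
4th-order convergence is verified against the exponential-decay closed
form.

**Reference parameters.** All turnover rates 0.05; k1 = 1, k2 = 0.01,
k3 = 1, k4 = 0.05 (k4·l_m = 0.5 with l_m = 10), k5 = 0.01, k6 = 0.01,
k7 = 0.1, k8 = 0.05, k9 = 7.5. Trigger length l_ds = 100 nt and
reference dose 1.0 molecule are this package's defaults, chosen so the
reference trajectory shows the canonical event order — dsRNA decays, 1°
siRNA peaks first, then pUG RNA, then 2° siRNA, while mRNA and pre-mRNA
dip below the knockdown threshold and recover once the intermediates
turn over. Large 1° siRNA bursts (dose·l_ds/22 ≳ 5 with these rate
constants) collapse mRNA before the 1° siRNA peak and invert that
order; dose and l_ds are plain configuration values for exploring that
regime.

**Metrics.** Knockdown threshold `m_kd` = 10 % of initial mRNA by
default; τ_kd is the first grid time with `m < m_kd` (an explicit
missing value — never 0 or ∞ — when the threshold is not crossed), t_kd
is dt × the number of grid points below threshold; m_min and sec_max
are the trajectory extremes.

**Experiments.**

- *Random sweep*: each selected parameter is multiplied by an
  independent log-uniform factor in [1/span, span] (span 10 by default,
  i.e. two orders of magnitude). Across such sweeps the time to
  knockdown and the duration of knockdown are essentially uncorrelated
  (|Spearman ρ| ≈ 0.3 < 0.5), and maximal 2° siRNA accumulation does
  not track minimal mRNA.
- *Transcription doubling*: both runs start from the same baseline
  steady state (computed with the original k9); 2·k9 applies from the
  moment of dosing, modeling upregulation during exposure. For the
  reference parameters τ_kd does not decrease and t_kd does not
  increase — more transcription means poorer knockdown.
- *Turnover experiment*: post-transcriptional mode (k3 = 0, so no
  pUG/2° siRNA branch and no transcriptional silencing), genes with
  identical steady-state mRNA m* but different turnover t_m (k9 rescaled
  as m*·t_m·(k7+t_p)/k7; for t_m = 0, k9 = 0 with mRNA initialized at
  m*), fixed dose 10 molecules. Minimum mRNA is non-decreasing in t_m:
  equal steady states with higher turnover imply higher production,
  hence faster resynthesis during knockdown.

Problem sizes used by the test suite (1,000-set sweeps at dt = 0.02,
horizons of 200–500 a.u. elsewhere) were chosen as the smallest runs
that make the qualitative claims statistically unambiguous.

## Phenotype scoring

Fraction-silenced counts (x silenced of n scored) get Wilson score
intervals with the Newcombe continuity correction, clipped to [0, 1]
with exact boundary behavior (lower bound 0 at x = 0, upper bound 1 at
x = n); a root-finding inversion of the continuity-corrected score test
is the oracle (agreement to 1e-6). Pairs of genotypes are compared with
the continuity-corrected two-proportion chi-squared test (identical to
R's `prop.test` default); when both margins agree exactly (e.g. both
groups fully silenced) the proportions are equal and p = 1 is returned.
Significance is called at α = 0.05 with no multiple-testing correction.
Because published two-proportion p-values vary with the exact procedure
(score vs chi-squared vs exact), the test suite validates significance
calls on published count pairs rather than p-value decimals; all 30
frozen pairs (and, during development, all 99 extractable pairs)
reproduce the published calls.

## In silico complementation

snpEff-annotated VCFs (one per strain) are read with pysam; gene and
impact come from the ANN entry matching the alternate allele (first
entry as fallback), malformed entries are skipped with a logged warning.
Variants are kept when their impact is HIGH or MODERATE and their site
(chrom, pos, ref, alt — the standard reading of "shared") occurs in
exactly one strain; shared sites are pre-existing background, removed
everywhere. Genes hit by surviving variants in ≥ 2 strains form
complementation groups, sorted by decreasing size then gene label, and
the result is independent of strain input order. Whether the original
analysis required distinct protein changes or merely distinct genomic
variants is unspecified; this implementation requires distinct genomic
variants only.

## Synthetic data

Generators are pure functions of configuration and seed. Phenotype
counts: binomial draws with success probability 1−noise where the
ground-truth network predicts silencing and noise otherwise (symmetric
by default; an asymmetric false-silenced rate is exposed). Variant
fixtures: shared background variants identical across strains, one
strain-unique HIGH/MODERATE variant per planted gene per strain at
globally distinct positions (drawn without replacement per chromosome),
plus LOW/MODIFIER decoys. Parameter grids reproduce the network
sampler's internal draw stream bit-for-bit at equal seeds.

What passing on synthetic data does **not** show: real phenotype counts
have scorer- and day-effects beyond binomial noise; real variant calls
contain genotyping errors, multi-allelic records, and genes hit by
chance in unrelated strains (the generators plant none of these); and
the kinetic model abstracts away spatial compartments, sequence-
dependent RdRP biochemistry, and stochasticity at low copy number.
Recovery of planted structure validates the pipeline logic, not its
robustness to those real-data features.

## Known limitations

- The network model culls consistent parameter regions; it does not
  infer path weights from quantitative phenotype data.
- The equilibrium classification count depends strongly on the sampling
  ranges, which are package defaults; only the range-independent
  qualitative claims are asserted.
- The ODE integrator uses a fixed step; very stiff parameter draws
  (products of large rate constants and pool sizes) need a smaller dt
  than the default.
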