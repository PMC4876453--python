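# Methods

This note records the models, the defaults and why, the numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## CCF model

For a mutation with alt count `a` of depth `n` in a sample of purity ρ,
local total copy number `q` and multiplicity `m` (mutant copies per tumour
cell), the expected allele fraction at cancer cell fraction `c` is
`f(c) = ρ·m·c / (ρ·q + (1−ρ)·2)`, clipped to [0, 1]. The posterior is the
binomial likelihood `Bin(a | n, f(c))` over a uniform grid on [0, 1]
(default pitch 0.01), normalised. Purity and copy number are *inputs*:
joint purity/ploidy estimation is deliberately out of scope, so this is the
conditional step of the standard purity-aware CCF conversion, not a
re-derivation of it.

Choices and caveats:

- **Grid pitch.** 0.01 suffices for single mutations at typical depths
  (posterior s.d. ≳ 0.02). Pooled cluster posteriors concentrate as
  1/√(members × depth); at depth 1000 with 10 members the s.d. is ~10⁻³,
  so the recovery benchmarks use a 0.001 grid. A grid coarser than the
  posterior collapses it to a point mass and destroys interval-based
  uncertainty, which is why `grid_step` is exposed everywhere.
- **Sequencing error.** The likelihood optionally perturbs the expected
  fraction to `f + ε(1−2f)` with ε = 10⁻³ (the pipeline default; 0 in the
  bare functions). Without it a single stray alt read assigns probability
  zero to CCF = 0, which in practice shatters low-CCF clusters into
  singletons. The synthetic read simulator has the matching ε switch,
  default off, so oracle tests run on the exact model.
- **Multiplicity.** Defaults to 1; when copy-number segments suggest m may
  exceed 1, an integer m in 1..q is chosen by maximising the grid-marginal
  likelihood. Sites inside germline copy-number variants are expected to be
  excluded upstream.
- **Mode tie-break.** Grid modes tie toward the larger CCF. Exact
  enumeration at depth 1000, true CCF 0.5, purity 1 gives
  P(|mode − 0.5| ≤ 0.05) = 0.9275 — slightly asymmetric because of binomial
  skew plus the upward tie-break; the test suite pins that exact value.

## Clustering

A finite mixture whose component "centres" are CCF vectors on the same
grid; a mutation's component likelihood is the product over samples of its
binomial grid likelihood at the centre. EM with an *exact* M-step (1-D grid
search per sample on the responsibility-weighted log-likelihood) guarantees
monotone ascent with no continuous optimisation. Model size k = 1..k_max is
chosen by BIC with k·n_samples + (k−1) parameters; ties go to smaller k.
Initialisation is k-means++ seeding on point-CCF vectors with 10 seeded
restarts, so results are deterministic given the seed. Mutations missing
from a sample are encoded as alt = 0 at that sample's median depth —
absence observed at typical power, not ignorance.

This is a simple, replaceable stand-in for Dirichlet-process-style
multi-sample CCF clustering: it resolves clusters separated by ≳ 0.1–0.2 in
CCF at depths of several hundred, and is not expected to separate clones
closer than the binomial noise floor.

## Clone phylogeny

Trees are over clusters (mutation sharing enters through clustering), with
a germline root whose only child is the trunk — the cluster with CCF ≥ 1−ε
in every sample (ε default 0.10, sized to absorb binomial noise at ~150×
depth). For ≤ 8 clusters all parent assignments are enumerated and filtered
by the per-sample constraints: parent CCF ≥ child CCF − ε, and children of
any node sum to at most its CCF + ε. Candidates are scored by Monte-Carlo
constraint-satisfaction mass: joint CCF draws from the cluster posteriors
(fixed seed), score = fraction of draws satisfying every constraint
strictly. Ties break by smaller mean violation, then shallower topology,
then lexicographic parent map — fully deterministic. When *no* tree
satisfies the constraints the least-violating tree is returned with
`constraint_flag=True` and its violation magnitude, because a diagnosable
answer on noisy data beats a hard failure.

Exclusive fractions are inclusive CCF minus the children's inclusive CCFs,
clipped at zero with the clip magnitude reported. Ambiguity is real: when a
small cluster's CCF fits under several parents in every sample, topology is
genuinely unidentifiable and the score expresses only mild preference; the
benchmarks therefore separate "the selected tree matches the exhaustive
oracle" (always required) from "the true topology is recovered" (checked on
a designed identifiable instance).

## Growth kinetics

Total circulating tumour cells = ALC/µl × blood volume in µl; blood volume
defaults to 5 l. ALC is treated as entirely CLL (an optional
tumour-fraction multiplier exists, default 1.0) — in heavily leukaemic
patients the approximation is good; in deep remission it overstates the
burden. Cell counts use *exclusive* fractions by default so clones sum to
the total (`ccf_mode=inclusive` is available). A clone is "detected" at a
sample when its point CCF ≥ 0.01, matching the 1%-of-burden upper bound
applied to undetected clones.

Fits, in the log domain throughout (natural log):

- two detected points: g = ln(N₂/N₁)/(t₂−t₁); s.d. and 95% CI from
  Monte-Carlo resamples of the CCF posteriors (counts refitted per draw,
  percentile interval). Draw counts are floored at one cell before logs.
- more points: OLS of ln N on t; the slope s.e. is reported, the CI again
  posterior-percentile when draws are available.
- shared rates: parallel lines (clone-specific intercepts, one slope) by
  least squares, for biologically coupled clones measured at few points.
- ALC-residual fit: burden minus all fitted clones, floored at 1 cell,
  fitted as one exponential — for clones seen too rarely to regress
  directly.
- upper bounds can enter a fit explicitly; if the earliest fitted point is
  a bound the rate is flagged as a *lower* bound on the truth.

N₀ = exp(intercept at day 0), with percentile CIs from the per-draw
intercepts, and "1 in N" formatting when a day-0 burden exists.
Extrapolation assumes the on-therapy rate was constant back to day 0; that
assumption is untestable from the data and is the dominant unquantified
uncertainty in any pre-treatment size estimate. Monte-Carlo draws default
to 1000 and every stochastic step takes an explicit seed.

## Assay statistics

Droplet occupancy is 1 − e^(−λ); its inverse recovers the loading from the
occupied fraction (single-template loading keeps occupancy < 30%,
λ ≈ 0.357). Mutant-cell frequencies get exact Clopper–Pearson binomial
intervals via beta quantiles — at frequencies near 10⁻⁶ normal
approximations are useless, and zero positives still yield an informative
upper bound 1 − 0.025^(1/n). Standard curves are least-squares lines of log
signal on log input frequency, inverted for unknowns, with out-of-range
flags. The single-cell caller regresses mutant-channel background on the
normal-allele level over known negatives, corrects, forms
f = m′/(normal + m′) and applies the 0.15/0.3 thresholds; boundary values
fall in "unclear" (conservative), 0/0 cells are excluded, and technical
replicates are averaged before calling.

## Synthetic data: what it does and does not show

The generator evolves a fixed clone tree with constant per-clone
exponential rates from day 0 (therapy start), derives ALC from summed
exclusive clone sizes over a 5 l volume, draws per-site depths Poisson
around the mean and alt counts binomially from the purity/copy-number
model, and emits assay signals with configurable background and dropout.
Clone genotypes are fixed at day 0 — no mutation acquisition over time —
and there is no lymph-node compartment, so redistribution lymphocytosis is
not modelled.

The reference benchmark scenario is a resistant relapse: trunk 5×10¹¹
cells at −0.2%/day, subclones of 27,000 and 4,000 cells at +1.5% and
+1.9%/day, draws at days 0/365/730/985, depth 1000, purity 0.9, 10
mutations per clone. The initial sizes were chosen once so the resistant
clones cross the 1% detection threshold only at the last two draws
(two-point fits, with the trunk on a four-point regression). On 200
replicates the median rate error is ~2×10⁻⁴/day, posterior-percentile CIs
cover the true rate ≳ 92% of the time, and back-extrapolated N₀ lands
within a factor of 3 of truth in > 99% of fits. Because simulator and
inference share the read-count model, these numbers demonstrate internal
consistency and correct uncertainty propagation — not robustness to
mis-specified purity, copy-number error, or non-constant real-world
kinetics. The benchmark groups mutations by their true clone: it measures
the kinetics machinery, while clustering is benchmarked separately at the
separations it is designed for.

## Known limitations

- Purity and allele-specific copy number are trusted inputs; errors in them
  propagate directly into CCFs and everything downstream.
- Exhaustive tree enumeration stops at 8 clusters.
- The constant-rate exponential is a modelling choice; logistic or
  Gompertz dynamics, treatment holidays and compartment exchange are out of
  scope.
- The clustering stand-in fixes one CCF vector per clone with purely
  binomial within-cluster dispersion; overdispersed real data may need the
  error-rate floor raised or a coarser grid.
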