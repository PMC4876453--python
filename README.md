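# clonekin

Clonal growth kinetics of treatment-resistant leukaemia from serial
sequencing.

When a chronic lymphocytic leukaemia (CLL) patient relapses on a targeted
kinase inhibitor, the resistant cells were usually not created by the drug —
they were already present, as a tiny subclone, on the day therapy began.
`clonekin` quantifies that story from routine data: serial somatic-mutation
read counts, allele-specific copy number, tumour purity and absolute
lymphocyte counts (ALC). It is a library (plus a thin `clonekin` CLI) for
computational oncologists who want per-clone growth rates and pre-treatment
clone sizes with honest uncertainties, and a fully synthetic patient
generator so every stage can be validated against known truth.

## The model

**Read counts → CCF.** A mutation with `a` alt reads out of `n` in a sample
of purity ρ, at local total copy number `q` with `m` mutant copies, has
expected allele fraction

    f(c) = ρ·m·c / (ρ·q + (1−ρ)·2)

for cancer cell fraction (CCF) `c`. A binomial likelihood on a discrete CCF
grid with a uniform prior gives a full posterior per mutation per sample.

**CCF → clones.** Mutations acquired in one clone share a CCF trajectory
across serial samples; a finite-mixture EM on the grid likelihood, with BIC
selecting the number of clusters, recovers the subclones.

**Clones → tree.** All rooted trees over the clusters are enumerated
(≤ 8 clusters) and filtered by the lineage constraints — a child's CCF
cannot exceed its parent's, and siblings cannot sum above their parent
(the pigeonhole principle). Candidates are scored by the posterior
probability mass of CCF configurations satisfying the constraints.

**Tree → kinetics.** Exclusive clone fractions times the total circulating
burden (ALC/µl × 5 l blood) give absolute clone sizes N_c(t). Each clone is
assumed to grow or decline exponentially at a constant rate during therapy:

    N_c(t) = N_c(0) · exp(g_c · t)

Two time points give the closed form g = ln(N₂/N₁)/(t₂−t₁) with a
Monte-Carlo s.d. from the CCF posteriors; more points give OLS in the log
domain with a regression s.e. Extrapolating the fitted line back to day 0
estimates the resistant clone's size at treatment initiation, reported as
cells, percent, and "1 in N" with posterior-based 95% CIs. Undetected
clones are capped at 1% of the tumour burden.

**Assay statistics.** The machinery of two orthogonal rare-cell validation
assays: droplet-digital quantification (Poisson loading 1 − e^(−λ), exact
Clopper–Pearson frequency CIs usable at 10⁻⁶, log-log standard-curve
inversion) and single-cell allele-specific genotyping (background
regression on known negatives; fractional mutant level < 0.15 → normal,
> 0.3 → mutant, between → unclear, 0/0 → excluded).

## Worked example

`examples/growth_kinetics.py` simulates a relapsing patient (trunk declining
at −0.2%/day; two resistant subclones growing at +1.0%/day and +1.5%/day
from 5×10⁸ and 10⁸ cells), sequences 24 mutations at depth 800 over four
draws, and runs the full pipeline:

```
clusters found: 3 (truth: 3); tree {1: 0, 2: 1, 3: 1} (0 = germline)

Per-clone kinetics (truth: -0.2%, +1.0%, +1.5% per day):
  clone 1: -0.22 +- 0.03 %/day (regression, 4 points)
  clone 2: +1.53 +- 0.02 %/day (two_point, 2 points)
            at therapy start: ~86,412,370 cells (1 in 5,793 of all tumour cells),
            95% CI [63,338,340, 109,649,313]
  clone 3: +1.02 +- 0.01 %/day (regression, 3 points)
            at therapy start: ~427,098,673 cells (1 in 1,172 of all tumour cells)

ALC fit quality (log-RMSE of summed clones vs observed counts): 0.041
```

All three rates land within ~0.03 percentage points of truth, the
back-extrapolated sizes within a factor of ~1.2, and the summed fitted
clones reproduce the lymphocyte counts (log-RMSE 0.04) — the signature that
constant exponential rates explain the whole trajectory. The other examples
cover simulation (`simulate_patient.py`), CCF posteriors
(`ccf_posteriors.py`), clustering + phylogeny (`cluster_and_tree.py`) and
the assay statistics (`rare_cell_assays.py`).

The same pipeline runs from the shell:

```bash
clonekin simulate --config sim.json --out-dir data/
clonekin run --config run.cfg --out-dir results/   # ccf/cluster/tree/kinetics TSVs
```

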