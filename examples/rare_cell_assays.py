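"""Rare-cell assay statistics: droplet counting and single-cell genotyping.

Droplet-digital screening counts mutant cells directly down to ~1 in a
million; a standard curve inverts fluorescence to frequency; and the
single-cell caller classifies each cell from its background-corrected
fractional mutant allele level.
"""

import numpy as np

import clonekin as ck

# --- Poisson loading: keep droplet occupancy below 30% ---------------------
lam = ck.occupancy_to_lambda(0.30)
print(f"30% occupied droplets corresponds to lambda = {lam:.4f} templates/droplet")
print("below this loading most positive droplets hold a single template\n")

# --- exact binomial frequency estimate --------------------------------------
est = ck.estimate_mutant_frequency(2, 10**6)
print("2 positive cells out of 1,000,000 screened:")
print(f"  frequency {est['frequency']:.2e} "
      f"(95% CI {est['ci_low']:.2e} - {est['ci_high']:.2e})")
fmt = ck.frequency_formats(2, 10**6)
print(f"  i.e. {fmt['percent']:.4f}% or 1 in {fmt['one_in_N']:,.0f} cells\n")

zero = ck.estimate_mutant_frequency(0, 10**6)
print(f"0 positives in 1,000,000 still bounds the frequency below "
      f"{zero['ci_high']:.2e}\n")

# --- standard curve: spike-ins at 1e-4, 1e-5, 1e-6 --------------------------
curve = [(1e-4, 400.0), (1e-5, 40.0), (1e-6, 4.0)]
out = ck.standard_curve_quantify(curve, observed_signal=12.6)
print(f"signal 12.6 against the spike-in curve -> input frequency "
      f"{out['frequency']:.2e} (extrapolated: {out['extrapolated']})\n")

# --- single-cell genotype calling -------------------------------------------
rng = np.random.default_rng(1)
normals = rng.normal(1.0, 0.05, 100)                      # known-negative cells
leak = 0.05 * normals + rng.normal(0, 0.01, 100)          # mutant-channel leakage
model = ck.fit_background_model(normals, leak)
print(f"background regression on 100 negative cells: "
      f"slope {model.slope:.3f}, intercept {model.intercept:.3f}")

for mutant, normal in [(0.08, 1.0), (0.9, 1.0), (0.3, 1.0), (0.0, 0.0)]:
    call = ck.call_single_cell_genotype(mutant, normal, model)
    print(f"  mutant level {mutant:.2f} / normal level {normal:.2f} -> {call}")
print("calls below 0.15 fractional mutant level are normal, above 0.3 mutant,")
print("in between unclear, and cells with no signal at all are excluded.")
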