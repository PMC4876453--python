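"""Generate a synthetic relapsing patient and inspect the ground truth.

A dominant trunk clone declines slowly on therapy while two small resistant
subclones expand exponentially; the absolute lymphocyte count (ALC) first
falls, then rises again as the resistant clones take over.
"""

import clonekin as ck

config = ck.SimConfig(
    parent={1: None, 2: 1, 3: 1},           # trunk with two resistant children
    initial_sizes={1: 5e11, 2: 27_000, 3: 4_000},   # cells at therapy start
    rates_per_day={1: -0.002, 2: 0.015, 3: 0.019},  # -0.2%, +1.5%, +1.9% per day
    sample_days=(0, 365, 730, 985),
    depth=1000,
    purity_per_sample=0.9,
    muts_per_clone=10,
    seed=11,
)
truth = ck.simulate_clonal_dynamics(config)

print("ALC (cells/ul) at each draw — the clinically observable burden:")
for day, alc in truth.alc_per_ul.items():
    print(f"  day {day:4d}: {alc:10,.0f}")

print("\nTrue inclusive CCF per clone (fraction of tumour cells in its lineage):")
print(truth.inclusive_ccf.round(4).to_string())

print("\nExclusive cell counts sum to ALC x blood volume at every day:")
print((truth.cells.sum(axis=0) / (truth.alc_per_ul * 5e6)).round(12).to_string())

obs = ck.simulate_sequencing(truth, seed=12)
print(f"\nSequenced {obs['mut_id'].nunique()} mutations x "
      f"{obs['sample'].nunique()} samples; first rows of read counts:")
print(obs[["sample", "day", "gene", "t_alt_count", "t_ref_count"]].head(4).to_string())
print("\nThe resistant clones are invisible in early samples (alt counts ~0) "
      "and dominate the final one — the raw material for kinetic inference.")
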