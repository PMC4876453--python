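"""End-to-end kinetics: from read counts to growth rates and pre-treatment sizes.

Runs the whole pipeline on a simulated relapsing patient and prints what a
clinician-facing report contains: per-clone exponential rates with
uncertainties, and how many cells each resistant clone comprised on the day
therapy began.
"""

import tempfile
from pathlib import Path

import pandas as pd

import clonekin as ck
from clonekin.io import PipelineConfig, write_table
from clonekin.pipeline import run_pipeline

config = ck.SimConfig(
    parent={1: None, 2: 1, 3: 1},
    initial_sizes={1: 5e11, 2: 5e8, 3: 1e8},
    rates_per_day={1: -0.002, 2: 0.010, 3: 0.015},
    sample_days=(0, 200, 400, 600),
    depth=800,
    purity_per_sample=0.9,
    muts_per_clone=8,
    seed=5,
)
truth = ck.simulate_clonal_dynamics(config)
obs = ck.simulate_sequencing(truth)

workdir = Path(tempfile.mkdtemp())
write_table(obs, workdir / "mutations.tsv")
write_table(pd.DataFrame({
    "sample": truth.sample_ids, "patient": "P1",
    "day": list(config.sample_days), "purity": config.purities(),
    "alc_per_ul": truth.alc_per_ul.to_numpy(),
}), workdir / "samples.tsv")

pipeline = PipelineConfig(
    mutations=str(workdir / "mutations.tsv"),
    samples=str(workdir / "samples.tsv"),
    seed=3, mc_draws=500,
)
report = run_pipeline(pipeline)["P1"]

print(f"clusters found: {report.clustering.k} (truth: 3); "
      f"tree {report.tree.parent} (0 = germline)")
print("\nPer-clone kinetics (truth: -0.2%, +1.0%, +1.5% per day):")
for clone, fit in sorted(report.fits.items()):
    print(f"  clone {clone}: {100 * fit.rate:+.2f} +- {100 * fit.rate_sd:.2f} %/day "
          f"({fit.method}, {fit.n_points} points)")
    if fit.one_in_n_at_day0:
        print(f"            at therapy start: ~{fit.n0:,.0f} cells "
              f"(1 in {fit.one_in_n_at_day0:,.0f} of all tumour cells), "
              f"95% CI [{fit.n0_ci[0]:,.0f}, {fit.n0_ci[1]:,.0f}]")
print(f"\nALC fit quality (log-RMSE of summed clones vs observed counts): "
      f"{report.alc_log_rmse:.3f}")
print("A small log-RMSE means constant per-clone exponential rates explain "
      "the patient's whole lymphocyte trajectory.")
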