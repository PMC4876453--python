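import numpy as np
import pandas as pd
import pytest

import clonekin as ck


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def three_clone_config():
    """Trunk plus two growing resistant subclones, four serial samples."""
    return ck.SimConfig(
        parent={1: None, 2: 1, 3: 1},
        initial_sizes={1: 5e11, 2: 5e8, 3: 1e8},
        rates_per_day={1: -0.002, 2: 0.01, 3: 0.015},
        sample_days=(0, 200, 400, 600),
        depth=800,
        purity_per_sample=0.9,
        muts_per_clone=8,
        seed=5,
    )


@pytest.fixture
def three_clone_truth(three_clone_config):
    return ck.simulate_clonal_dynamics(three_clone_config)


@pytest.fixture
def patient_tables(tmp_path, three_clone_config, three_clone_truth):
    """Mutations + samples TSVs for the three-clone patient, on disk."""
    truth = three_clone_truth
    obs = ck.simulate_sequencing(truth)
    mut_path = tmp_path / "mutations.tsv"
    sam_path = tmp_path / "samples.tsv"
    obs.to_csv(mut_path, sep="\t", index=False)
    pd.DataFrame({
        "sample": truth.sample_ids,
        "patient": "P1",
        "day": list(three_clone_config.sample_days),
        "purity": three_clone_config.purities(),
        "alc_per_ul": truth.alc_per_ul.to_numpy(),
    }).to_csv(sam_path, sep="\t", index=False)
    return {"mutations": mut_path, "samples": sam_path, "truth": truth}
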