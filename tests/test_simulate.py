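"""The synthetic patient generator: conservation, determinism, closed forms."""

import numpy as np
import pytest

import clonekin as ck


def one_clone(g=0.0, n0=1e10, days=(0, 100, 350), **kw):
    return ck.SimConfig(
        parent={1: None}, initial_sizes={1: n0}, rates_per_day={1: g},
        sample_days=days, **kw,
    )


class TestClonalDynamics:
    def test_static_clone_gives_constant_alc(self):
        # 1e10 cells in 5 l -> 2,000 lymphocytes per microlitre at every draw
        truth = ck.simulate_clonal_dynamics(one_clone(g=0.0, n0=1e10))
        assert np.allclose(truth.alc_per_ul, 2000.0)

    def test_exponential_decline_closed_form(self):
        truth = ck.simulate_clonal_dynamics(one_clone(g=-0.002, days=(0, 350)))
        ratio = truth.cells.loc[1, 350] / truth.cells.loc[1, 0]
        assert ratio == pytest.approx(np.exp(-0.7), rel=1e-12)

    def test_exclusive_counts_sum_to_alc_times_volume(self, three_clone_truth):
        total = three_clone_truth.cells.sum(axis=0)
        vol_ul = three_clone_truth.config.blood_volume_l * 1e6
        assert np.allclose(total, three_clone_truth.alc_per_ul * vol_ul)

    def test_inclusive_ccf_sums_descendants(self, three_clone_truth):
        t = three_clone_truth
        expect = (t.cells.loc[1] + t.cells.loc[2] + t.cells.loc[3]) / t.cells.sum(axis=0)
        assert np.allclose(t.inclusive_ccf.loc[1], expect)
        assert np.allclose(t.inclusive_ccf.loc[1], 1.0)  # trunk covers everything

    def test_deterministic_given_seed(self, three_clone_config):
        a = ck.simulate_clonal_dynamics(three_clone_config)
        b = ck.simulate_clonal_dynamics(three_clone_config)
        assert a.cells.equals(b.cells)
        assert a.mutations.equals(b.mutations)

    def test_larger_rate_grows_more(self):
        cfgs = [one_clone(g=g, days=(0, 100)) for g in (0.01, 0.03)]
        ratios = [
            ck.simulate_clonal_dynamics(c).cells.loc[1, 100] / 1e10 for c in cfgs
        ]
        assert ratios[1] > ratios[0] > 1.0

    @pytest.mark.parametrize("mutator", [
        lambda c: c.parent.update({1: 2, 2: 1}),              # cycle
        lambda c: c.initial_sizes.update({1: 0.0}),           # non-positive size
        lambda c: setattr(c, "sample_days", (100, 100)),      # non-increasing days
        lambda c: setattr(c, "purity_per_sample", 0.0),       # purity out of range
    ])
    def test_invalid_configs_rejected(self, mutator):
        cfg = ck.SimConfig(
            parent={1: None, 2: 1}, initial_sizes={1: 1e9, 2: 1e6},
            rates_per_day={1: 0.0, 2: 0.01}, sample_days=(0, 100),
        )
        mutator(cfg)
        with pytest.raises(ValueError):
            ck.simulate_clonal_dynamics(cfg)


class TestSequencing:
    def test_clonal_het_af_half(self, rng):
        # CCF=1, purity=1, q=2, m=1 -> E[af] = 0.5
        truth = ck.simulate_clonal_dynamics(
            one_clone(days=(0,), muts_per_clone=50, depth=2000)
        )
        obs = ck.simulate_sequencing(truth, purity=1.0, seed=1)
        af = obs["t_alt_count"] / (obs["t_alt_count"] + obs["t_ref_count"])
        assert af.mean() == pytest.approx(0.5, abs=0.01)

    def test_zero_ccf_gives_zero_alt(self):
        cfg = ck.SimConfig(
            parent={1: None, 2: 1}, initial_sizes={1: 1e9, 2: 1e-12},
            rates_per_day={1: 0.0, 2: 0.0}, sample_days=(0,), muts_per_clone=20,
        )
        truth = ck.simulate_clonal_dynamics(cfg)
        obs = ck.simulate_sequencing(truth, seed=3)
        assert (obs.loc[obs["clone"] == 2, "t_alt_count"] == 0).all()

    def test_observed_af_concentrates_at_expectation(self):
        # CCF=0.5, purity=0.8 -> E[af]=0.2; depth 1000 keeps 95% within +-0.04
        cfg = ck.SimConfig(
            parent={1: None, 2: 1}, initial_sizes={1: 5e9, 2: 5e9},
            rates_per_day={1: 0.0, 2: 0.0}, sample_days=(0,),
            muts_per_clone=200, depth=1000, purity_per_sample=0.8,
        )
        truth = ck.simulate_clonal_dynamics(cfg)
        obs = ck.simulate_sequencing(truth, seed=11)
        sub = obs[obs["clone"] == 2]
        af = sub["t_alt_count"] / (sub["t_alt_count"] + sub["t_ref_count"])
        assert np.mean(np.abs(af - 0.2) <= 0.04) >= 0.95

    def test_depth_must_be_positive(self, three_clone_truth):
        with pytest.raises(ValueError, match="depth"):
            ck.simulate_sequencing(three_clone_truth, depth=0)


class TestAssaySimulator:
    def test_zero_prevalence_zero_positives(self):
        cfg = ck.SimConfig(
            parent={1: None, 2: 1}, initial_sizes={1: 1e9, 2: 1e-12},
            rates_per_day={1: 0.0, 2: 0.0}, sample_days=(0,),
        )
        truth = ck.simulate_clonal_dynamics(cfg)
        droplets, _ = ck.simulate_assay_data(truth, day=0, target_clone=2,
                                             n_cells_droplet=10**6, seed=4)
        assert droplets["n_positive"].iloc[0] == 0

    def test_rare_clone_positive_count_in_poisson_band(self):
        # prevalence 1e-4 in 1e6 screened cells -> ~100 positives;
        # Poisson(100) 99% band is about [75, 127]
        cfg = ck.SimConfig(
            parent={1: None, 2: 1}, initial_sizes={1: 1e9, 2: 1e5},
            rates_per_day={1: 0.0, 2: 0.0}, sample_days=(0,),
        )
        truth = ck.simulate_clonal_dynamics(cfg)
        counts = [
            ck.simulate_assay_data(truth, 0, 2, 10**6, seed=s)[0]["n_positive"].iloc[0]
            for s in range(20)
        ]
        assert all(75 <= c <= 127 for c in counts)

    def test_rejects_nonpositive_screen(self, three_clone_truth):
        with pytest.raises(ValueError):
            ck.simulate_assay_data(three_clone_truth, 0, 1, n_cells_droplet=0)
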