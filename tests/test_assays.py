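"""Droplet quantification and single-cell genotype-calling statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonekin as ck
from clonekin.evaluation import frequency_ci_coverage


class TestPoissonLoading:
    def test_zero_lambda_zero_occupancy(self):
        assert ck.poisson_occupancy(0.0) == 0.0

    def test_thirty_percent_occupancy_lambda(self):
        # the single-template loading rule: <30% occupied droplets
        assert ck.occupancy_to_lambda(0.30) == pytest.approx(-np.log(0.7))
        assert ck.occupancy_to_lambda(0.30) == pytest.approx(0.3567, abs=1e-4)

    def test_ln2_gives_half(self):
        assert ck.poisson_occupancy(np.log(2)) == pytest.approx(0.5)

    # above lambda ~ 8 the occupancy saturates at 1.0 in float64 and the
    # round trip loses absolute precision; real loadings sit well below 1
    @given(lam=st.floats(0.0, 8.0))
    @settings(max_examples=100, deadline=None)
    def test_inverse_composes_to_identity(self, lam):
        assert ck.occupancy_to_lambda(ck.poisson_occupancy(lam)) == pytest.approx(
            lam, abs=1e-12
        )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ck.poisson_occupancy(-0.1)


class TestFrequencyEstimation:
    def test_zero_positives_exact_upper_bound(self):
        out = ck.estimate_mutant_frequency(0, 10**6)
        assert out["frequency"] == 0.0
        assert out["ci_low"] == 0.0
        # closed form: 1 - 0.025**(1/n)
        assert out["ci_high"] == pytest.approx(1 - 0.025 ** (1 / 10**6), rel=1e-6)
        assert out["ci_high"] == pytest.approx(3.69e-6, rel=0.01)

    def test_point_estimate_is_ratio(self):
        assert ck.estimate_mutant_frequency(3, 2 * 10**6)["frequency"] == pytest.approx(1.5e-6)

    def test_all_positive_reaches_one(self):
        out = ck.estimate_mutant_frequency(100, 100)
        assert out["frequency"] == 1.0 and out["ci_high"] == 1.0

    def test_more_positives_than_cells_rejected(self):
        with pytest.raises(ValueError):
            ck.estimate_mutant_frequency(5, 4)

    @pytest.mark.parametrize("freq", [1e-4, 1e-5])
    def test_exact_ci_coverage_smoke(self, freq):
        out = frequency_ci_coverage(freq, 10**6, n_seeds=100, base_seed=9)
        assert out["coverage_percent"] >= 93.0


class TestStandardCurve:
    CURVE = [(1e-4, 400.0), (1e-5, 40.0), (1e-6, 4.0)]  # perfect power law

    def test_curve_point_returns_itself(self):
        out = ck.standard_curve_quantify(self.CURVE, 40.0)
        assert out["frequency"] == pytest.approx(1e-5, rel=1e-9)
        assert not out["extrapolated"]

    def test_log_midpoint_inverts_geometrically(self):
        signal = np.sqrt(40.0 * 4.0)  # halfway in log space between 1e-5 and 1e-6
        out = ck.standard_curve_quantify(self.CURVE, signal)
        assert out["frequency"] == pytest.approx(np.sqrt(1e-5 * 1e-6), rel=1e-9)
        assert out["frequency"] == pytest.approx(3.16e-6, rel=0.01)

    def test_extrapolation_flagged(self):
        assert ck.standard_curve_quantify(self.CURVE, 4000.0)["extrapolated"]

    def test_identical_inputs_rejected(self):
        with pytest.raises(ValueError):
            ck.standard_curve_quantify([(1e-5, 10.0), (1e-5, 12.0)], 11.0)


class TestBackgroundModel:
    def test_zero_background_in_clean_negatives(self):
        model = ck.fit_background_model(np.array([1.0, 1.1, 0.9, 1.2]),
                                        np.zeros(4))
        assert model.slope == 0.0 and model.intercept == 0.0
        assert model.residual_sd == 0.0

    def test_recovers_simulated_slope(self, rng):
        normal = rng.uniform(0.5, 1.5, size=100)
        mutant = 0.05 * normal + rng.normal(0.0, 0.01, size=100)
        model = ck.fit_background_model(normal, mutant)
        assert model.slope == pytest.approx(0.05, abs=0.01)

    def test_constant_offset_only(self):
        model = ck.fit_background_model(np.array([1.0, 1.0, 1.0]),
                                        np.array([0.2, 0.2, 0.2]))
        assert model.slope == 0.0
        assert model.intercept == pytest.approx(0.2)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="3"):
            ck.fit_background_model(np.array([1.0, 1.0]), np.array([0.0, 0.0]))


class TestGenotypeCalls:
    @pytest.mark.parametrize("f,expected", [
        (0.10, "normal"),
        (0.1499, "normal"),
        (0.15, "unclear"),    # boundaries fall in the unclear band
        (0.20, "unclear"),
        (0.30, "unclear"),
        (0.3001, "mutant"),
        (0.40, "mutant"),
        (1.00, "mutant"),
        (0.00, "normal"),
    ])
    def test_threshold_partition_exact(self, f, expected):
        # construct signals giving fractional mutant level exactly f
        mutant = f
        normal = 1.0 - f
        assert ck.call_single_cell_genotype(mutant, normal) == expected

    def test_double_dropout_excluded(self):
        assert ck.call_single_cell_genotype(0.0, 0.0) == "excluded"

    def test_background_correction_rescues_normal_cell(self):
        model = ck.BackgroundModel(slope=0.3, intercept=0.0, residual_sd=0.0, n_cells=10)
        # raw f = 0.3/1.3 = 0.23 (unclear); corrected mutant level is 0
        assert ck.call_single_cell_genotype(0.3, 1.0) == "unclear"
        assert ck.call_single_cell_genotype(0.3, 1.0, model) == "normal"

    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError):
            ck.call_single_cell_genotype(-0.1, 1.0)

    def test_replicates_averaged_before_calling(self):
        rep1 = pd.DataFrame({"cell_id": ["a"], "mutant_level": [0.0], "normal_level": [1.0]})
        rep2 = pd.DataFrame({"cell_id": ["a"], "mutant_level": [1.0], "normal_level": [1.0]})
        merged = ck.consolidate_replicates([rep1, rep2])
        assert merged.loc[0, "mutant_level"] == pytest.approx(0.5)
        calls = ck.call_genotypes(merged)
        assert calls.loc[0, "call"] == "mutant"  # 0.5/1.5 = 0.33 > 0.3

    def test_simulated_assay_end_to_end(self, three_clone_truth):
        droplets, cells = ck.simulate_assay_data(
            three_clone_truth, day=600, target_clone=3,
            n_cells_droplet=10**5, n_cells_singlecell=300, seed=8,
        )
        est = ck.estimate_mutant_frequency(
            int(droplets["n_positive"].iloc[0]), int(droplets["cells_screened"].iloc[0])
        )
        true_prev = droplets["true_prevalence"].iloc[0]
        assert est["ci_low"] <= true_prev <= est["ci_high"]
        negatives = cells[~cells["true_mutant"]]
        model = ck.fit_background_model(negatives)
        calls = ck.call_genotypes(cells, model)
        confident = calls[calls["call"].isin(["normal", "mutant"])]
        agreement = (
            (confident["call"] == "mutant") == confident["true_mutant"]
        ).mean()
        assert agreement >= 0.95
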