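"""Growth kinetics: burden arithmetic, exponential fits, extrapolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonekin as ck
from clonekin.kinetics import _ols_line


def traj(days, cells, clone=1, detected=None, bounds=None):
    detected = [True] * len(days) if detected is None else detected
    t = ck.CloneTrajectory(clone_id=clone)
    for i, (d, n) in enumerate(zip(days, cells)):
        t.points.append(ck.TrajectoryPoint(
            day=d, cells=n if detected[i] else 0.0,
            ci_low=0.0 if not detected[i] else n, ci_high=n,
            detected=detected[i],
            upper_bound=None if detected[i] else (bounds or {}).get(d),
        ))
    return t


class TestBurdenArithmetic:
    def test_zero_alc_zero_cells(self):
        assert ck.total_cll_cells(0.0) == 0.0

    def test_patient_scale_alc(self):
        # a normal ALC of 1,800/ul in 5 l of blood is 9e9 lymphocytes
        meta = ck.SampleMeta("S", "P", 0, 1.0, 1800.0)
        assert ck.total_cll_cells(meta) == pytest.approx(9e9)
        assert ck.total_cll_cells(20_000.0) == pytest.approx(1e11)

    def test_fraction_times_burden(self):
        metas = [ck.SampleMeta("S1", "P", 0, 1.0, 1800.0),
                 ck.SampleMeta("S2", "P", 100, 1.0, 2000.0)]
        trajs = ck.clone_cell_counts({1: np.array([0.5, 1.0])}, metas)
        assert trajs[1].points[0].cells == pytest.approx(4.5e9)
        assert trajs[1].points[1].cells == pytest.approx(1e10)
        assert all(p.detected for p in trajs[1].points)

    def test_zero_fraction_undetected_with_bound(self):
        metas = [ck.SampleMeta("S1", "P", 0, 1.0, 20_000.0)]
        trajs = ck.clone_cell_counts({1: np.array([0.0])}, metas)
        p = trajs[1].points[0]
        assert p.cells == 0.0 and not p.detected
        assert p.upper_bound == pytest.approx(1e9)  # 1% of 1e11

    @pytest.mark.parametrize("alc,frac,expected", [
        (20_000.0, 0.01, 1e9),
        (2_000.0, 0.05, 5e8),
        (0.0, 0.01, 0.0),
    ])
    def test_upper_bound_values(self, alc, frac, expected):
        assert ck.undetected_upper_bound(alc, frac) == pytest.approx(expected)

    def test_upper_bound_fraction_range(self):
        with pytest.raises(ValueError):
            ck.undetected_upper_bound(1000.0, bound_fraction=1.5)


class TestFitGrowthRate:
    def test_two_point_closed_form(self):
        fit = ck.fit_growth_rate(traj([0, 100], [1e4, 1e4 * np.e**1.5]))
        assert fit.rate == pytest.approx(0.015, abs=1e-12)
        assert fit.method == "two_point"

    def test_equal_counts_zero_rate(self):
        fit = ck.fit_growth_rate(traj([0, 50], [2e6, 2e6]))
        assert fit.rate == 0.0

    def test_noiseless_regression_exact(self):
        days = np.array([0.0, 100.0, 250.0, 400.0])
        fit = ck.fit_growth_rate(traj(days, 1e5 * np.exp(0.033 * days)))
        assert fit.rate == pytest.approx(0.033, abs=1e-12)
        assert fit.method == "regression"
        assert fit.n0 == pytest.approx(1e5, rel=1e-9)

    @given(
        n1=st.floats(1e2, 1e12), n2=st.floats(1e2, 1e12),
        t1=st.integers(0, 500), dt=st.integers(1, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_two_point_formula_equals_ols(self, n1, n2, t1, dt):
        days = np.array([t1, t1 + dt], dtype=float)
        closed = np.log(n2 / n1) / dt
        slope, _, _ = _ols_line(days, np.log([n1, n2]))
        assert slope == pytest.approx(closed, abs=1e-12)

    def test_insufficient_points_signalled(self):
        with pytest.raises(ck.InsufficientDataError):
            ck.fit_growth_rate(traj([0], [1e5]))

    def test_monte_carlo_ci_brackets_rate(self, rng):
        days = [100, 200]
        cells = [1e8, 1e8 * np.exp(0.02 * 100)]
        draws = np.array(cells) * rng.lognormal(0.0, 0.05, size=(500, 2))
        fit = ck.fit_growth_rate(traj(days, cells), count_draws=draws)
        assert fit.rate_ci[0] < 0.02 < fit.rate_ci[1]
        assert fit.rate_sd > 0

    def test_upper_bound_start_flags_lower_bound(self):
        t = traj([0, 300], [0.0, 1e9], detected=[False, True], bounds={0: 1e7})
        fit = ck.fit_growth_rate(t, include_upper_bounds=True)
        assert fit.rate_is_lower_bound
        assert fit.rate == pytest.approx(np.log(1e9 / 1e7) / 300)

    def test_more_final_cells_never_lower_rate(self):
        days = [0, 100, 200]
        base = [1e6, 2e6, 4e6]
        f0 = ck.fit_growth_rate(traj(days, base)).rate
        f1 = ck.fit_growth_rate(traj(days, [1e6, 2e6, 8e6])).rate
        assert f1 >= f0


class TestSharedRate:
    def test_exact_shared_exponentials_match_individual(self):
        days = np.array([0.0, 100.0, 200.0, 300.0])
        t1 = traj(days, 1e6 * np.exp(0.02 * days), clone=1)
        t2 = traj(days, 5e7 * np.exp(0.02 * days), clone=2)
        fits = ck.fit_shared_rate({1: t1, 2: t2}, groups=[[1, 2]])
        assert fits[1].rate == pytest.approx(0.02, abs=1e-12)
        assert fits[1].rate == fits[2].rate
        assert fits[1].n0 == pytest.approx(1e6, rel=1e-9)

    def test_singleton_group_matches_plain_fit(self):
        t1 = traj([0, 100, 220], [1e6, 3e6, 2e7])
        single = ck.fit_growth_rate(t1)
        shared = ck.fit_shared_rate({1: t1}, groups=[[1]])
        assert shared[1].rate == pytest.approx(single.rate, abs=1e-12)

    def test_shared_fit_beats_individual_under_noise(self):
        # pooling two clones with one true rate lowers the rate MSE
        days = np.array([0.0, 120.0, 240.0, 360.0])
        rng = np.random.default_rng(17)
        err_shared, err_solo = [], []
        for _ in range(200):
            noise = rng.lognormal(0.0, 0.1, size=(2, 4))
            t1 = traj(days, 1e6 * np.exp(0.02 * days) * noise[0], clone=1)
            t2 = traj(days, 4e7 * np.exp(0.02 * days) * noise[1], clone=2)
            fits = ck.fit_shared_rate({1: t1, 2: t2}, groups=[[1, 2]])
            err_shared.append((fits[1].rate - 0.02) ** 2)
            err_solo.append((ck.fit_growth_rate(t1).rate - 0.02) ** 2)
            err_solo.append((ck.fit_growth_rate(t2).rate - 0.02) ** 2)
        assert np.mean(err_shared) < np.mean(err_solo)

    def test_degenerate_design_rejected(self):
        t1 = traj([50, 50], [1e6, 2e6], clone=1)
        with pytest.raises(ValueError):
            ck.fit_shared_rate({1: t1}, groups=[[1]])


class TestAlcResidualFit:
    def test_single_clone_equals_alc_fit(self):
        days = np.array([0.0, 100.0, 300.0])
        alc = 2000.0 * np.exp(0.01 * days)
        fit = ck.fit_rate_from_alc(days, alc, other_fits=[])
        assert fit.rate == pytest.approx(0.01, abs=1e-12)
        assert fit.method == "alc_fit"

    def test_residual_clone_recovered(self):
        # known declining clone + hidden grower; residual fit finds g=0.04
        days = np.array([0.0, 200.0, 400.0, 600.0])
        known = ck.GrowthFit(clone_id=1, rate=-0.002, rate_sd=0.0,
                             intercept=np.log(4e11), n_points=4, method="regression")
        rng = np.random.default_rng(3)
        hidden = 1e8 * np.exp(0.04 * days) * rng.lognormal(0.0, 0.05, size=4)
        alc = (known.predict(days) + hidden) / 5e6
        fit = ck.fit_rate_from_alc(days, alc, other_fits=[known])
        assert fit.rate == pytest.approx(0.04, abs=0.002)

    def test_no_residual_signalled(self):
        days = np.array([0.0, 100.0])
        known = ck.GrowthFit(clone_id=1, rate=0.0, rate_sd=0.0,
                             intercept=np.log(1e10), n_points=2, method="two_point")
        with pytest.raises(ck.NoResidualError):
            ck.fit_rate_from_alc(days, np.array([1000.0, 1000.0]), other_fits=[known])


class TestExtrapolation:
    def test_resistant_clone_back_extrapolation(self):
        # a clone at 5e11 cells on day 985 growing at 1.9%/day started at ~3,700
        g = 0.019
        fit = ck.fit_growth_rate(traj([885, 985], [5e11 * np.exp(-0.019 * 100), 5e11]))
        fit = ck.extrapolate_initial_size(fit)
        assert fit.rate == pytest.approx(g, abs=1e-12)
        assert fit.n0 == pytest.approx(5e11 * np.exp(-g * 985), rel=1e-9)
        assert fit.n0 == pytest.approx(3.7e3, rel=0.01)

    def test_flat_line_gives_geometric_mean(self):
        fit = ck.fit_growth_rate(traj([100, 200, 300], [1e6, 1e6, 1e6]))
        fit = ck.extrapolate_initial_size(fit)
        assert fit.rate == 0.0
        assert fit.n0 == pytest.approx(1e6, rel=1e-9)

    def test_one_in_n_formatting_attached(self):
        fit = ck.fit_growth_rate(traj([0, 100], [8.7e7, 8.7e7]))
        fit = ck.extrapolate_initial_size(fit, day0_total_cells=1.392e11)
        assert fit.one_in_n_at_day0 == pytest.approx(1600)

    def test_n0_ci_covers_truth_in_simulation(self, rng):
        # posterior-draw CIs cover the true N0 in >= 90% of replicates
        days = np.array([600.0, 900.0])
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            true = 1e5 * np.exp(0.015 * days)
            obs_cells = true * rng.lognormal(0.0, 0.1, size=2)
            draws = obs_cells * rng.lognormal(0.0, 0.1, size=(400, 2))
            fit = ck.fit_growth_rate(traj(days, obs_cells), count_draws=draws)
            fit = ck.extrapolate_initial_size(fit, days=days, count_draws=draws)
            hits += fit.n0_ci[0] <= 1e5 <= fit.n0_ci[1]
        assert hits / n_rep >= 0.90


class TestPredictAlc:
    def test_exact_single_clone_zero_rmse(self):
        days = np.array([0.0, 100.0, 200.0])
        fit = ck.GrowthFit(clone_id=1, rate=0.01, rate_sd=0.0,
                           intercept=np.log(1e10), n_points=3, method="regression")
        pred, rmse = ck.predict_alc([fit], days,
                                    observed_alc_per_ul=1e10 * np.exp(0.01 * days) / 5e6)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_omitting_grower_underestimates_late_alc(self):
        days = np.array([0.0, 300.0, 600.0])
        stable = ck.GrowthFit(clone_id=1, rate=0.0, rate_sd=0.0,
                              intercept=np.log(1e10), n_points=3, method="regression")
        grower = ck.GrowthFit(clone_id=2, rate=0.01, rate_sd=0.0,
                              intercept=np.log(1e9), n_points=3, method="regression")
        obs, _ = ck.predict_alc([stable, grower], days)
        partial, rmse = ck.predict_alc([stable], days, observed_alc_per_ul=obs)
        assert partial[-1] < obs[-1]
        assert rmse > 0


class TestFrequencyFormats:
    def test_one_in_five_hundred_thousand(self):
        out = ck.frequency_formats(1, 500_000)
        assert out["percent"] == pytest.approx(0.0002)
        assert out["one_in_N"] == 500_000

    def test_whole_population(self):
        out = ck.frequency_formats(100, 100)
        assert out["percent"] == 100.0 and out["one_in_N"] == 1

    def test_reported_resistant_clone_scale(self):
        out = ck.frequency_formats(8.7e7, 1.392e11)
        assert out["one_in_N"] == pytest.approx(1600)

    def test_rejects_more_cells_than_total(self):
        with pytest.raises(ValueError):
            ck.frequency_formats(2, 1)
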