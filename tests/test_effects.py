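import warnings

import numpy as np
import pytest

import tempmort as tm
from tempmort.basis import BasisSpec, default_knots
from tempmort.crossbasis import build_crossbasis, make_lag_spec
from tempmort.effects import (
    ExposureResponseCurve,
    default_grid,
    find_mmt,
    predict_curve,
    rr_at_percentiles,
    run_category_analysis,
)
from tempmort.simplify import ThresholdSpec, fit_threshold_model


@pytest.fixture(scope="module")
def sthr_fit(sthr_series):
    series, truth = sthr_series
    fit, curve, cb = fit_threshold_model(series, ThresholdSpec(high=30.0))
    return series, fit, curve, cb


class TestPredictCurve:
    def test_rr_one_at_reference(self, sthr_fit):
        series, fit, curve, cb = sthr_fit
        i = int(np.argmin(np.abs(curve.grid - 30.0)))
        assert curve.rr[i] == pytest.approx(1.0, abs=1e-9)
        assert curve.se[i] == pytest.approx(0.0, abs=1e-12)
        assert curve.ci_low[i] == pytest.approx(1.0, abs=1e-9)

    def test_sthr_closed_form_two_degrees_above(self, sthr_fit):
        series, fit, curve, cb = sthr_fit
        from tempmort.simplify import cumulative_threshold_slopes

        beta = cumulative_threshold_slopes(fit, cb)["heat"]["slope"]
        i = int(np.argmin(np.abs(curve.grid - 32.0)))
        t = curve.grid[i]
        assert curve.rr[i] == pytest.approx(np.exp(beta * (t - 30.0)), rel=1e-9)

    def test_curve_flat_below_threshold(self, sthr_fit):
        series, fit, curve, cb = sthr_fit
        below = curve.grid <= 30.0
        np.testing.assert_allclose(curve.rr[below], 1.0, atol=1e-12)

    def test_ci_contains_point_estimate(self, sthr_fit):
        _, _, curve, _ = sthr_fit
        assert np.all(curve.ci_low <= curve.rr + 1e-12)
        assert np.all(curve.rr <= curve.ci_high + 1e-12)

    def test_recentering_shifts_by_constant(self, sthr_series):
        series, _ = sthr_series
        table, curves, fits = run_category_analysis(series, ["all"])
        fit = fits["all"]
        cfg = tm.AnalysisConfig()
        pred = default_knots(series.tmean, cfg.pred_df)
        cb = build_crossbasis(series.tmean, pred,
                              make_lag_spec(cfg.lag_df, cfg.max_lag), cfg.max_lag)
        grid = default_grid(series.tmean)
        c1 = predict_curve(fit, cb, grid, ref=28.0)
        c2 = predict_curve(fit, cb, grid, ref=31.0)
        diff = c1.log_rr - c2.log_rr
        assert np.max(np.abs(diff - diff[0])) < 1e-10

    def test_extrapolation_warns(self, sthr_series):
        series, _ = sthr_series
        _, curves, fits = run_category_analysis(series, ["all"])
        cfg = tm.AnalysisConfig()
        pred = default_knots(series.tmean, cfg.pred_df)
        cb = build_crossbasis(series.tmean, pred,
                              make_lag_spec(cfg.lag_df, cfg.max_lag), cfg.max_lag)
        with pytest.warns(UserWarning, match="outside basis boundary"):
            predict_curve(fits["all"], cb, [series.tmean.max() + 5], ref=29.0)

    def test_delta_method_matches_monte_carlo(self, sthr_series):
        """Delta-method SE equals the SD of the contrast under coefficient
        draws from MVN(beta, V), within 5% relative error."""
        series, _ = sthr_series
        _, curves, fits = run_category_analysis(series, ["all"])
        fit = fits["all"]
        cfg = tm.AnalysisConfig()
        pred = default_knots(series.tmean, cfg.pred_df)
        cb = build_crossbasis(series.tmean, pred,
                              make_lag_spec(cfg.lag_df, cfg.max_lag), cfg.max_lag)
        t99 = np.percentile(series.tmean, 99)
        curve = predict_curve(fit, cb, [t99], ref=29.0)
        from tempmort.crossbasis import crossbasis_contrast

        v = crossbasis_contrast(pred, cb.lag_spec, cb.max_lag, t99, 29.0)
        rng = np.random.default_rng(99)
        draws = rng.multivariate_normal(
            fit.block_params("crossbasis"), fit.block_cov("crossbasis"), 10000
        )
        mc_se = (draws @ v).std(ddof=1)
        assert curve.se[0] == pytest.approx(mc_se, rel=0.05)


class TestFindMmt:
    def _curve(self, y, grid=None):
        grid = np.arange(23.5, 33.35, 0.1) if grid is None else grid
        return ExposureResponseCurve(grid, np.asarray(y, float),
                                     np.zeros(len(grid)), ref_temp=28.0)

    def test_parabola_vertex(self):
        grid = np.arange(23.5, 33.35, 0.1)
        c = self._curve((grid - 30.0) ** 2, grid)
        assert find_mmt(c) == pytest.approx(30.0, abs=1e-9)

    def test_tie_breaks_to_lowest_temperature(self):
        grid = np.arange(24.0, 32.05, 0.1)
        y = np.minimum((grid - 26.0) ** 2, (grid - 30.0) ** 2)
        c = self._curve(y, grid)
        assert find_mmt(c) == pytest.approx(26.0, abs=1e-9)

    def test_flat_curve_returns_midpoint_with_warning(self):
        grid = np.arange(24.0, 32.05, 0.1)
        c = self._curve(np.zeros(len(grid)), grid)
        with pytest.warns(UserWarning, match="flat"):
            mmt = find_mmt(c)
        assert mmt == pytest.approx((grid[0] + grid[-1]) / 2, abs=0.1)

    def test_search_window_restricts_argmin(self):
        grid = np.arange(24.0, 32.05, 0.1)
        y = (grid - 24.0) ** 2  # global min at the boundary
        c = self._curve(y, grid)
        assert find_mmt(c, t_lo=26.0, t_hi=31.0) == pytest.approx(26.0, abs=1e-9)


class TestRrTable:
    def test_rr_one_when_percentile_equals_mmt(self, sthr_fit):
        series, fit, curve, cb = sthr_fit
        # pick the grid point at the MMT (largest grid temp inside the null
        # region) and force a pseudo-percentile exactly there
        t0 = float(curve.grid[curve.grid <= 30.0][-1])
        curve.mmt = t0
        import dataclasses

        s2 = dataclasses.replace(series, tmean=np.full(len(series), t0),
                                 rh=series.rh, deaths=series.deaths, dates=series.dates)
        rows = rr_at_percentiles(curve, s2, percentiles=(50,))
        assert rows.iloc[0]["rr"] == pytest.approx(1.0, abs=1e-6)

    def test_monotone_above_mmt(self, sthr_fit):
        series, fit, curve, cb = sthr_fit
        tab = rr_at_percentiles(curve, series, percentiles=(95, 99))
        assert tab.iloc[1]["rr"] >= tab.iloc[0]["rr"]

    def test_slope_recovery_two_degrees_above_threshold(self, sthr_series):
        """Estimated RR 2 °C above the h=30 threshold within 2 SE of 1.21."""
        series, truth = sthr_series
        fit, curve, cb = fit_threshold_model(series, ThresholdSpec(high=30.0))
        i = int(np.argmin(np.abs(curve.grid - 32.0)))
        log_rr, se = curve.log_rr[i], curve.se[i]
        target = np.log(1.10) * (curve.grid[i] - 30.0)
        assert abs(log_rr - target) < 2 * se


class TestRunCategoryAnalysis:
    def test_categories_are_independent(self):
        cfg = tm.SyntheticConfig(
            n_years=2,
            categories=(tm.CategoryConfig("young", 0.6), tm.CategoryConfig("old", 0.4)),
        )
        series, _ = tm.generate_dataset(cfg, seed=77)
        assert (series.deaths["young"] + series.deaths["old"]
                == series.deaths["all"]).all()
        table, curves, fits = run_category_analysis(series, ["young", "old"])
        assert set(table["category"]) == {"young", "old"}
        assert not np.allclose(fits["young"].params, fits["old"].params)

    def test_empty_category_list_errors(self, small_series):
        with pytest.raises(ValueError):
            run_category_analysis(small_series, [])

    def test_all_zero_category_skipped(self, small_series):
        import dataclasses

        deaths = small_series.deaths.copy()
        deaths["ghost"] = 0
        s = dataclasses.replace(small_series, deaths=deaths)
        with pytest.warns(UserWarning, match="ghost"):
            table, curves, fits = run_category_analysis(s, ["all", "ghost"])
        assert "ghost" not in fits

    def test_rr_table_shows_one_at_each_mmt(self, sthr_series):
        series, _ = sthr_series
        table, curves, fits = run_category_analysis(series, ["all"])
        for cat, curve in curves.items():
            i = int(np.argmin(np.abs(curve.grid - curve.mmt)))
            assert curve.rr[i] == pytest.approx(1.0, abs=1e-9)
            assert (table[table.category == cat]["mmt"] == curve.mmt).all()

    def test_category_slope_ordering_recovered(self):
        """A category with double the heat slope shows the larger 99th-pct RR
        in most replicates."""
        wins, n_sims = 0, 12
        for r in range(n_sims):
            cfg = tm.SyntheticConfig(
                n_years=3,
                surface=tm.TruthSurface(kind="sthr", threshold_high=30.0,
                                        heat_slope=np.log(1.10)),
                mortality=tm.MortalityConfig(overdispersion=1.5),
                categories=(tm.CategoryConfig("young", 0.6, 0.5),
                            tm.CategoryConfig("elderly", 0.4, 2.0)),
            )
            series, _ = tm.generate_dataset(cfg, seed=600 + r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table, _, _ = run_category_analysis(series, ["young", "elderly"])
            p99 = table[table.percentile == 99].set_index("category")["rr"]
            wins += p99["elderly"] > p99["young"]
        assert wins >= 0.75 * n_sims
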