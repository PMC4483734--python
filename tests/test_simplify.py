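import warnings

import numpy as np
import pytest

import tempmort as tm
from tempmort.effects import ExposureResponseCurve
from tempmort.simplify import (
    ThresholdSpec,
    cumulative_threshold_slopes,
    fit_threshold_model,
    locate_minima,
    run_transition,
    threshold_grid_search,
)


def _curve(grid, y):
    return ExposureResponseCurve(np.asarray(grid, float), np.asarray(y, float),
                                 np.zeros(len(grid)), ref_temp=28.0)


class TestLocateMinima:
    def test_w_shape_two_minima(self):
        grid = np.arange(24.0, 32.05, 0.1)
        y = np.minimum((grid - 26.0) ** 2, (grid - 30.0) ** 2)
        assert locate_minima(_curve(grid, y)) == pytest.approx([26.0, 30.0], abs=1e-9)

    def test_u_shape_single_minimum(self):
        grid = np.arange(24.0, 32.05, 0.1)
        y = (grid - 29.0) ** 2
        assert locate_minima(_curve(grid, y)) == pytest.approx([29.0], abs=1e-9)

    def test_monotone_curve_empty(self):
        grid = np.arange(24.0, 32.05, 0.1)
        assert locate_minima(_curve(grid, grid * 0.1)) == []

    def test_plateau_collapses_to_lowest_temperature(self):
        grid = np.arange(0.0, 1.05, 0.1)
        y = np.array([2, 1, 0, 0, 0, 1, 2, 3, 4, 5, 6], float)
        assert locate_minima(_curve(grid, y)) == pytest.approx([0.2], abs=1e-9)


class TestFitThresholdModel:
    def test_null_simulation_slopes_within_2se(self):
        cfg = tm.SyntheticConfig(n_years=3,
                                 mortality=tm.MortalityConfig(overdispersion=1.5))
        series, _ = tm.generate_dataset(cfg, seed=41)
        fit, curve, cb = fit_threshold_model(
            series, ThresholdSpec(low=27.0, high=30.0))
        slopes = cumulative_threshold_slopes(fit, cb)
        for arm in ("cold", "heat"):
            assert abs(slopes[arm]["slope"]) < 2 * slopes[arm]["se"]

    def test_sthr_curve_flat_below_loglinear_above(self, sthr_series):
        series, _ = sthr_series
        fit, curve, cb = fit_threshold_model(series, ThresholdSpec(high=30.0))
        below = curve.grid <= 30.0
        np.testing.assert_allclose(curve.log_rr[below], 0.0, atol=1e-12)
        above = curve.grid > 30.0
        slope = curve.log_rr[above] / (curve.grid[above] - 30.0)
        assert np.ptp(slope) < 1e-9  # exactly log-linear

    def test_noiseless_loglinear_slope_recovered(self):
        """Deterministic limit: huge baseline, no overdispersion, no nuisance
        -> slope estimate equals truth to high precision."""
        surf = tm.TruthSurface(kind="sthr", threshold_high=30.0,
                               heat_slope=0.08, lag_weights=(1.0,))
        cfg = tm.SyntheticConfig(
            n_years=3, surface=surf,
            mortality=tm.MortalityConfig(baseline=5e5, overdispersion=1.0,
                                         seasonal_amplitude=0.0,
                                         dow_multipliers=(1.0,) * 7),
        )
        series, _ = tm.generate_dataset(cfg, seed=42)
        from tempmort.crossbasis import make_lag_spec

        # same-day truth, same-day model: the lag structure is exactly representable
        fit, curve, cb = fit_threshold_model(
            series, ThresholdSpec(high=30.0), lag_spec=make_lag_spec(1, 0), max_lag=0)
        slope = cumulative_threshold_slopes(fit, cb)["heat"]["slope"]
        assert slope == pytest.approx(0.08, abs=5e-4)

    def test_threshold_outside_range_rejected(self, small_series):
        with pytest.raises(ValueError, match="outside data range"):
            fit_threshold_model(small_series, ThresholdSpec(high=50.0))


class TestGridSearch:
    def test_single_candidate_returned(self, sthr_series):
        series, _ = sthr_series
        spec, trace = threshold_grid_search(series, None, [30.0])
        assert spec.high == 30.0 and spec.kind == "sthr"
        assert len(trace) == 1

    def test_empty_grid_errors(self, small_series):
        with pytest.raises(ValueError, match="empty candidate grid"):
            threshold_grid_search(small_series, None, [])

    def test_sthr_truth_threshold_recovered(self, sthr_series):
        series, _ = sthr_series
        spec, trace = threshold_grid_search(series, None, np.arange(28.5, 31.55, 0.1))
        assert abs(spec.high - 30.0) <= 0.5

    def test_genuine_cold_arm_keeps_dthr(self):
        """Truth with real cold and heat arms retains the double threshold in
        most replicates."""
        kept, n_sims = 0, 8
        surf = tm.TruthSurface(kind="dthr", threshold_low=27.0, threshold_high=30.0,
                               heat_slope=np.log(1.15), cold_slope=np.log(1.20))
        for r in range(n_sims):
            cfg = tm.SyntheticConfig(surface=surf,
                                     mortality=tm.MortalityConfig(overdispersion=1.5))
            series, _ = tm.generate_dataset(cfg, seed=700 + r)
            spec, trace = threshold_grid_search(
                series, np.arange(26.5, 27.55, 0.25), np.arange(29.5, 30.55, 0.25))
            kept += spec.kind == "dthr"
        assert kept >= 0.8 * n_sims


class TestRunTransition:
    def test_sthr_truth_ends_in_sthr_near_truth(self):
        cfg = tm.SyntheticConfig(
            n_years=3,
            surface=tm.TruthSurface(kind="sthr", threshold_high=30.0,
                                    heat_slope=np.log(1.15)),
            mortality=tm.MortalityConfig(overdispersion=1.5),
        )
        series, _ = tm.generate_dataset(cfg, seed=55)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_transition(series)
        final = [n for n in report.stages if n.startswith("sthr_ncs")][-1]
        high = report.stages[final]["thresholds"][1]
        assert abs(high - 30.0) <= 1.0
        assert report.stages["ncs_ncs"]["qaic"] >= min(
            st["qaic"] for st in report.stages.values())

    def test_null_truth_flags_stage_equivalence(self):
        cfg = tm.SyntheticConfig(n_years=3,
                                 mortality=tm.MortalityConfig(overdispersion=1.5))
        series, _ = tm.generate_dataset(cfg, seed=56)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_transition(series)
        qaics = [st["qaic"] for st in report.stages.values()]
        # threshold stages cannot beat a null truth by a meaningful margin
        assert max(qaics) - min(qaics) < 25

    def test_threshold_stages_centered_at_threshold(self):
        cfg = tm.SyntheticConfig(
            n_years=3,
            surface=tm.TruthSurface(kind="sthr", threshold_high=30.0,
                                    heat_slope=np.log(1.15)),
            mortality=tm.MortalityConfig(overdispersion=1.5),
        )
        series, _ = tm.generate_dataset(cfg, seed=57)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_transition(series)
        for name, st in report.stages.items():
            if name == "ncs_ncs":
                continue
            curve = st["curve"]
            high = st["thresholds"][1]
            i = int(np.argmin(np.abs(curve.grid - high)))
            assert curve.rr[i] == pytest.approx(1.0, abs=1e-9)

    def test_all_stages_share_usable_rows(self):
        # same max_lag everywhere: criteria are computed on identical rows
        cfg = tm.SyntheticConfig(n_years=2)
        series, _ = tm.generate_dataset(cfg, seed=58)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_transition(series)
        n_obs = {st["fit"].n_obs for st in report.stages.values()}
        assert len(n_obs) == 1
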