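"""ARIMA stage: differencing, ADF, fitting, order selection, diagnostics, forecasts."""

import numpy as np
import pytest

from uaprogress.scoring import WeeklyGroupScore
from uaprogress.timeseries import (
    AnalysisConfig,
    ArimaOrder,
    DegenerateSeriesError,
    adf_test,
    box_pierce,
    difference,
    fit_arima,
    forecast,
    run_two_phase_analysis,
    select_order,
    split_phases,
    undifference,
)


def ar1(phi, n, rng, sigma=1.0):
    x = np.zeros(n)
    e = rng.standard_normal(n) * sigma
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


class TestDifference:
    @pytest.mark.parametrize(
        "d,expected", [(0, [1, 2, 4, 7]), (1, [1, 2, 3]), (2, [1, 1])]
    )
    def test_known_values(self, d, expected):
        assert difference([1, 2, 4, 7], d).tolist() == expected

    def test_too_short_series_is_an_error(self):
        with pytest.raises(ValueError, match="too short"):
            difference([1.0, 2.0], 2)

    def test_undifference_inverts_exactly(self):
        rng = np.random.default_rng(0)
        for d in (1, 2, 3):
            x = rng.standard_normal(30)
            initial = [difference(x, k)[0] for k in range(d)]
            rebuilt = undifference(difference(x, d), initial)
            np.testing.assert_allclose(rebuilt, x, atol=1e-12)


class TestAdf:
    def test_white_noise_rejects_unit_root(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            adf_test(rng.standard_normal(500)).reject_unit_root for _ in range(40)
        )
        assert rejections >= 36  # >= 90% power

    def test_random_walk_rarely_rejects(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            adf_test(np.cumsum(rng.standard_normal(500))).reject_unit_root
            for _ in range(40)
        )
        assert rejections <= 4  # <= 10% size

    def test_auto_lag_rule(self):
        rng = np.random.default_rng(3)
        result = adf_test(rng.standard_normal(217))
        assert result.lags_used == int(np.floor(216 ** (1 / 3)))

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            adf_test([1.0] * 50)

    def test_too_short_for_lags_is_an_error(self):
        with pytest.raises(ValueError, match="too short"):
            adf_test(np.arange(12.0), lags=5)


class TestFitArima:
    def test_ar1_coefficient_recovery(self):
        rng = np.random.default_rng(4)
        fit = fit_arima(ar1(0.6, 500, rng), ArimaOrder(1, 0, 0))
        assert fit.ar_coefficients[0] == pytest.approx(0.6, abs=0.1)

    def test_mean_model_intercept_matches_sample_mean(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(400) + 2.5
        fit = fit_arima(x, ArimaOrder(0, 0, 0))
        assert fit.intercept == pytest.approx(x.mean(), abs=3 / np.sqrt(400))

    def test_insufficient_data_for_order_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_arima([1.0, 2.0, 1.5, 2.5, 2.0], ArimaOrder(3, 4, 7))

    def test_residual_length_excludes_differenced_points(self):
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.standard_normal(100))
        fit = fit_arima(x, ArimaOrder(0, 1, 0))
        assert len(fit.residuals) == len(x) - 1

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(7)
        x = ar1(0.4, 200, rng)
        a = fit_arima(x, ArimaOrder(1, 0, 1))
        b = fit_arima(x, ArimaOrder(1, 0, 1))
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.ar_coefficients, b.ar_coefficients)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            ArimaOrder(-1, 0, 0)


class TestSelectOrder:
    def test_recovers_ar2_majority_of_replicates(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_reps = 10
        for _ in range(n_reps):
            e = rng.standard_normal(500)
            x = np.zeros(500)
            for t in range(2, 500):
                # complex-root AR(2): clearly identified second-order dynamics
                x[t] = 0.6 * x[t - 1] - 0.5 * x[t - 2] + e[t]
            order = select_order(x, max_p=3, max_d=1, max_q=2)
            hits += order.p == 2 and order.d == 0
        assert hits > n_reps / 2

    def test_white_noise_selects_parsimonious_stationary_model(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(10):
            order = select_order(rng.standard_normal(400), max_p=2, max_d=1, max_q=2)
            hits += order.d == 0 and order.p + order.q <= 1
        assert hits > 5

    def test_degenerate_grid_on_stationary_series(self):
        rng = np.random.default_rng(10)
        order = select_order(rng.standard_normal(300), max_p=0, max_d=0, max_q=0)
        assert order.as_tuple() == (0, 0, 0)


class TestBoxPierce:
    def test_zero_autocorrelation_gives_zero_statistic_and_unit_p(self):
        # period-4 pattern 1,0,-1,0: every lag-1 product is zero, so the
        # sample autocorrelation at lag 1 vanishes exactly
        x = np.array([1.0, 0.0, -1.0, 0.0] * 25)
        result = box_pierce(x, 1)
        assert result.q_statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_q_statistic_matches_brute_force_oracle(self):
        def oracle(x, m):
            x = np.asarray(x, float)
            xc = x - x.mean()
            denom = float(xc @ xc)
            rho = [float(xc[k:] @ xc[:-k]) / denom for k in range(1, m + 1)]
            return len(x) * float(np.sum(np.square(rho)))

        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.standard_normal(int(rng.integers(50, 300)))
            result = box_pierce(x, 10)
            assert result.q_statistic == pytest.approx(oracle(x, 10), abs=1e-10)
            assert 0.0 <= result.p_value <= 1.0

    def test_df_subtracts_fitted_params(self):
        rng = np.random.default_rng(12)
        result = box_pierce(rng.standard_normal(100), 10, n_fitted_params=3)
        assert result.df == 7

    def test_lags_must_exceed_fitted_params(self):
        with pytest.raises(ValueError, match="n_lags"):
            box_pierce(np.zeros(100) + np.arange(100), 3, n_fitted_params=3)

    def test_needs_more_residuals_than_lags(self):
        with pytest.raises(ValueError, match="residuals"):
            box_pierce([1.0, 2.0, 0.5], 5)

    def test_ljung_box_option(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(200)
        lb = box_pierce(x, 10, method="ljung-box")
        bp = box_pierce(x, 10, method="box-pierce")
        assert lb.q_statistic >= bp.q_statistic  # Ljung-Box inflates small-sample Q


class TestSplitPhases:
    def test_52_week_series_splits_into_26_26(self):
        first, second = split_phases(np.arange(52.0), split_week=27)
        assert (len(first), len(second)) == (26, 26)

    def test_minimal_split(self):
        first, second = split_phases(np.arange(10.0), split_week=2)
        assert (len(first), len(second)) == (1, 9)

    def test_concatenation_reproduces_input(self):
        x = np.random.default_rng(14).standard_normal(52)
        first, second = split_phases(x, 27)
        np.testing.assert_array_equal(np.concatenate([first, second]), x)

    @pytest.mark.parametrize("split", [0, 1, 53])
    def test_out_of_range_split_is_an_error(self, split):
        with pytest.raises(ValueError):
            split_phases(np.arange(52.0), split)


class TestForecast:
    def test_mean_model_forecasts_the_intercept(self):
        rng = np.random.default_rng(15)
        fit = fit_arima(rng.standard_normal(300) + 1.0, ArimaOrder(0, 0, 0))
        fc = forecast(fit, 6)
        np.testing.assert_allclose(fc.point_forecasts, fit.intercept, atol=1e-8)

    def test_random_walk_forecast_is_flat_at_last_value(self):
        rng = np.random.default_rng(16)
        x = np.cumsum(rng.standard_normal(150))
        fit = fit_arima(x, ArimaOrder(0, 1, 0))
        fc = forecast(fit, 5)
        np.testing.assert_allclose(fc.point_forecasts, x[-1], atol=1e-8)

    def test_interval_width_grows_with_horizon_for_integrated_model(self):
        rng = np.random.default_rng(17)
        fit = fit_arima(np.cumsum(rng.standard_normal(150)), ArimaOrder(0, 1, 0))
        fc = forecast(fit, 10)
        widths = fc.upper - fc.lower
        assert widths[9] >= widths[0]
        assert np.all(np.diff(widths) >= -1e-9)


def weekly_from_values(values):
    return [
        WeeklyGroupScore(i + 1, 0 if v is None else int(np.sign(v)),
                         0 if v is None else 1, v)
        for i, v in enumerate(values)
    ]


class TestTwoPhaseAnalysis:
    @staticmethod
    def simulated_weekly(p_positive_high=0.1, seed=19, n_patients=200):
        from uaprogress.scoring import group_weekly_scores
        from uaprogress.simulate import ProtocolConfig, SimulationConfig, simulate_cohort

        proto = ProtocolConfig()
        cohort = simulate_cohort(
            proto,
            SimulationConfig(
                n_patients=n_patients, p_positive_high=p_positive_high, seed=seed
            ),
        )
        return group_weekly_scores(cohort, proto.program_length)

    def test_high_abstinence_first_segment_forecast_trend_nonnegative(self):
        weekly = self.simulated_weekly(p_positive_high=0.1)
        report = run_two_phase_analysis(weekly)
        points = report["segments"][0]["forecast"]["point"]
        slope = np.polyfit(np.arange(len(points)), points, 1)[0]
        assert slope >= -1e-6

    def test_fixed_orders_populate_both_portmanteau_p_values(self):
        weekly = self.simulated_weekly(seed=21)
        config = AnalysisConfig(orders=(ArimaOrder(3, 4, 7), ArimaOrder(2, 2, 3)))
        with pytest.warns(UserWarning, match="fragile"):
            report = run_two_phase_analysis(weekly, config)
        orders = [tuple(s["order"].values()) for s in report["segments"]]
        assert orders == [(3, 4, 7), (2, 2, 3)]
        for seg in report["segments"]:
            assert 0.0 <= seg["portmanteau"]["p_value"] <= 1.0

    def test_constant_series_fails_with_degenerate_message(self):
        weekly = weekly_from_values([0.0] * 52)
        with pytest.raises(DegenerateSeriesError, match="constant"):
            run_two_phase_analysis(weekly)

    def test_missing_weeks_are_filled_and_counted(self):
        rng = np.random.default_rng(20)
        values = [
            float(np.clip(0.3 + 0.3 * rng.standard_normal(), -1, 1)) if i % 2 else None
            for i in range(52)
        ]
        weekly = weekly_from_values(values)
        config = AnalysisConfig(fill_policy="interpolate")
        report = run_two_phase_analysis(weekly, config)
        assert report["n_weeks_filled"] == 26
        assert report["n_weeks"] == 52
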