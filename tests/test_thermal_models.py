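import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import onionfly as of
from onionfly.thermal_models import ExposureAssay, FitError


class TestLactinRate:
    def test_zero_exactly_at_thermal_maximum(self, table1):
        p = table1["lactin"]
        assert of.lactin_rate(p.t_max, p) == 0.0

    def test_published_sdt_rate_at_16c(self, table1):
        # direct evaluation of the two-exponential expression
        p = table1["lactin"]
        expected = np.exp(p.rho * 16.0) - np.exp(p.rho * p.t_max - (p.t_max - 16.0) / p.delta_t)
        assert of.lactin_rate(16.0, p) == pytest.approx(expected)
        assert of.lactin_rate(16.0, p) == pytest.approx(0.600, abs=0.005)

    def test_clamped_to_zero_above_thermal_maximum(self, table1):
        p = table1["lactin"]
        temps = np.linspace(p.t_max, 40.0, 50)
        assert np.all(of.lactin_rate(temps, p) == 0.0)

    def test_upper_limit_root_matches_published_22_1(self, table1):
        assert of.lactin_upper_limit(table1["lactin"]) == pytest.approx(22.1, abs=0.05)

    def test_invalid_delta_t_rejected(self):
        with pytest.raises(ValueError):
            of.ThermalResponseParams(rho=0.1, t_max=30.0, delta_t=0.0)


class TestExposureFit:
    def test_exact_line_through_origin(self):
        assay = ExposureAssay(
            temperature=10.0, exposure_days=(1, 2, 5), completed_proportion=(0.1, 0.2, 0.5)
        )
        fit = of.fit_exposure(assay)
        assert fit.slope_a == pytest.approx(0.1)
        assert fit.p50 == pytest.approx(5.0)
        assert fit.valid

    def test_all_zero_proportions_flagged_invalid(self):
        assay = ExposureAssay(
            temperature=30.0, exposure_days=(1, 2, 5), completed_proportion=(0.0, 0.0, 0.0)
        )
        fit = of.fit_exposure(assay)
        assert not fit.valid
        assert fit.p50 is None

    def test_noisy_known_slope_recovered(self):
        rng = np.random.default_rng(11)
        days = np.array([1.0, 2.0, 3.0])
        props = np.clip(0.25 * days + rng.normal(0, 0.01, days.size), 0, 1)
        fit = of.fit_exposure(
            ExposureAssay(temperature=5.6, exposure_days=tuple(days), completed_proportion=tuple(props))
        )
        assert fit.slope_a == pytest.approx(0.25, abs=0.02)
        assert fit.p50 == pytest.approx(2.0, rel=0.1)

    def test_p50_halves_when_slope_doubles(self):
        days = (1.0, 2.0, 3.0)
        f1 = of.fit_exposure(ExposureAssay(2.0, days, tuple(0.1 * d for d in days)))
        f2 = of.fit_exposure(ExposureAssay(2.0, days, tuple(0.2 * d for d in days)))
        assert f2.p50 == pytest.approx(f1.p50 / 2.0)

    def test_single_point_rejected(self):
        with pytest.raises(FitError):
            of.fit_exposure(ExposureAssay(10.0, (1.0,), (0.2,)))


class TestNormalizeTimes:
    @pytest.mark.parametrize(
        "days,p50,expected",
        [([1, 2, 5], 2.0, [0.5, 1.0, 2.5]), ([2.0], 2.0, [1.0]), ([], 2.0, [])],
    )
    def test_elementwise_division(self, days, p50, expected):
        assert of.normalize_times(days, p50) == pytest.approx(expected)

    def test_non_positive_p50_rejected(self):
        with pytest.raises(ValueError):
            of.normalize_times([1.0], 0.0)


class TestWeibullCdf:
    def test_zero_at_origin(self, table1):
        assert of.weibull_cdf(0.0, table1["weibull"]) == 0.0

    def test_63_2_percent_at_alpha(self, table1):
        d = table1["weibull"]
        assert of.weibull_cdf(d.alpha, d) == pytest.approx(1 - np.exp(-1))

    def test_matches_scipy_weibull_min(self, table1):
        # independent cross-check of the CDF form against scipy.stats
        d = table1["weibull"]
        x = np.linspace(0.0, 4.0, 37)
        ours = of.weibull_cdf(x, d)
        ref = stats.weibull_min.cdf(x, c=d.beta, scale=d.alpha)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_direct_evaluation_at_unit_time(self, table1):
        assert of.weibull_cdf(1.0, table1["weibull"]) == pytest.approx(0.542, abs=0.001)

    @given(
        alpha=st.floats(0.2, 5.0),
        beta=st.floats(0.3, 8.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_cdf_at_alpha_identity_for_any_parameters(self, alpha, beta):
        d = of.CompletionDistribution(alpha=alpha, beta=beta)
        assert of.weibull_cdf(alpha, d) == pytest.approx(1 - np.exp(-1), rel=1e-9)


class TestFitLactin:
    def test_refit_of_published_pupal_points(self):
        df = of.load_fixture("pupal_development_points")
        fit = of.fit_lactin(list(zip(df["temperature_c"], 1.0 / df["development_days"])))
        assert fit.r_squared == pytest.approx(0.94, abs=0.01)
        # fit is deterministic: repeated calls agree exactly
        again = of.fit_lactin(list(zip(df["temperature_c"], 1.0 / df["development_days"])))
        assert again.params == fit.params

    def test_noise_free_parameter_recovery(self, table2):
        p = table2["lactin"]
        temps = np.linspace(8.0, 34.0, 12)
        rates = of.lactin_rate(temps, p)
        fit = of.fit_lactin(list(zip(temps, rates)))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-8)
        assert fit.params.rho == pytest.approx(p.rho, rel=0.01)
        assert fit.params.t_max == pytest.approx(p.t_max, rel=0.01)
        assert fit.params.delta_t == pytest.approx(p.delta_t, rel=0.01)

    def test_underdetermined_input_rejected(self):
        with pytest.raises(FitError):
            of.fit_lactin([(10.0, 0.02), (20.0, 0.08)])


class TestFitWeibull:
    def test_noise_free_parameter_recovery(self, table1):
        d = table1["weibull"]
        x = np.linspace(0.1, 3.0, 15)
        y = of.weibull_cdf(x, d)
        fit = of.fit_weibull(list(zip(x, y)))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-8)
        assert fit.params.alpha == pytest.approx(d.alpha, rel=0.01)
        assert fit.params.beta == pytest.approx(d.beta, rel=0.01)

    def test_exponential_special_case(self):
        x = np.linspace(0.05, 4.0, 20)
        y = 1 - np.exp(-x)  # alpha = beta = 1
        fit = of.fit_weibull(list(zip(x, y)))
        assert fit.params.alpha == pytest.approx(1.0, abs=1e-6)
        assert fit.params.beta == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "points",
        [
            [(1.0, 0.5)],
            [(1.0, 0.2), (1.0, 0.4), (1.0, 0.6)],
        ],
    )
    def test_degenerate_inputs_rejected(self, points):
        with pytest.raises(FitError):
            of.fit_weibull(points)


class TestDensitySurface:
    def test_rows_above_thermal_maximum_are_zero(self, table1):
        grid = of.density_surface(table1["lactin"], table1["weibull"], [23.0, 30.0], horizon=20)
        assert np.all(grid == 0.0)

    def test_rows_nonnegative_sum_below_one_cumsum_monotone(self, table1):
        temps = np.arange(2.0, 26.0, 2.0)
        grid = of.density_surface(table1["lactin"], table1["weibull"], temps, horizon=30)
        assert np.all(grid >= 0.0)
        assert np.all(grid.sum(axis=1) <= 1.0 + 1e-12)
        cum = np.cumsum(grid, axis=1)
        assert np.all(np.diff(cum, axis=1) >= -1e-15)

    def test_day2_cumulative_at_16c(self, table1):
        # CDF evaluated at two days' accumulated age at constant 16 °C
        p, d = table1["lactin"], table1["weibull"]
        grid = of.density_surface(p, d, [16.0], horizon=2)
        expected = of.weibull_cdf(2.0 * of.lactin_rate(16.0, p), d)
        assert grid[0].sum() == pytest.approx(expected)
        assert grid[0].sum() == pytest.approx(0.66, abs=0.01)

    def test_horizon_must_be_positive(self, table1):
        with pytest.raises(ValueError):
            of.density_surface(table1["lactin"], table1["weibull"], [16.0], horizon=0)
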