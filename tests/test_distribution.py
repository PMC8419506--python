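"""Distribution functions: validity, round trips, limits, oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from nexf import (ParamVector, cdf, hazard, logsf, order_stat_cdf,
                  order_stat_pdf, pdf, quantile, reversed_hazard, rvs, sf)


def frechet_cdf(x, a, l):
    return math.exp(-((a / x) ** l))


class TestValidity:
    def test_validity_triad_random_thetas(self, random_thetas):
        """CDF monotone with 0/1 limits, density nonnegative, on 200 thetas."""
        for th in random_thetas:
            x = np.geomspace(th.alpha / 50.0, th.alpha * 50.0, 60)
            G = cdf(x, th)
            assert np.all(np.diff(G) >= -1e-12)
            assert G[0] >= 0.0 and G[-1] <= 1.0
            assert float(cdf(quantile(1 - 1e-9, th), th)) > 1.0 - 1e-6
            assert float(cdf(quantile(1e-9, th), th)) < 1e-6
            assert np.all(pdf(x, th) >= 0.0)

    @pytest.mark.parametrize("theta", [(0.5, 0.5, 0.5), (1, 2, 1.5), (3, 3, 3)])
    def test_pdf_integrates_to_one(self, theta):
        val, _ = integrate.quad(lambda x: float(pdf(x, theta)), 0.0, np.inf,
                                limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_cdf_equals_integral_of_pdf(self):
        """Eq-level check: G(x0) equals adaptive quadrature of g over (0, x0]."""
        th = (1.0, 2.0, 1.5)
        for x0 in (0.4, 1.0, 2.5):
            val, _ = integrate.quad(lambda x: float(pdf(x, th)), 0.0, x0,
                                    limit=200, epsabs=1e-12)
            assert float(cdf(x0, th)) == pytest.approx(val, abs=1e-8)

    def test_pdf_is_derivative_of_cdf(self):
        th = (1.0, 2.0, 1.5)
        x, h = 1.3, 1e-6
        fd = (float(cdf(x + h, th)) - float(cdf(x - h, th))) / (2 * h)
        assert float(pdf(x, th)) == pytest.approx(fd, abs=1e-6)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            cdf(-1.0, (1, 1, 1))
        with pytest.raises(ValueError):
            cdf(1.0, (-1, 1, 1))
        with pytest.raises(ValueError):
            quantile(1.5, (1, 1, 1))


class TestBaselineCollapse:
    """beta -> 0 recovers the plain Frechet distribution."""

    def test_cdf_collapse(self):
        assert float(cdf(1.0, (1, 0, 1))) == pytest.approx(math.exp(-1))
        for x in (0.3, 1.0, 4.0):
            assert float(cdf(x, (1.2, 0, 2.0))) == pytest.approx(
                frechet_cdf(x, 1.2, 2.0), rel=1e-12)

    def test_pdf_collapse(self):
        a, l = 0.8, 1.7
        for x in (0.5, 1.0, 3.0):
            expect = (l / x) * (a / x) ** l * math.exp(-((a / x) ** l))
            assert float(pdf(x, (a, 0, l))) == pytest.approx(expect, rel=1e-12)

    def test_quantile_collapse(self):
        for p in (0.1, 0.5, 0.9):
            assert float(quantile(p, (2.0, 0, 1.5))) == pytest.approx(
                2.0 * (-math.log(p)) ** (-1 / 1.5), rel=1e-12)

    def test_small_beta_continuity(self):
        """cdf is continuous in beta at 0 (limiting reference)."""
        x = 1.3
        assert float(cdf(x, (1, 1e-12, 1))) == pytest.approx(
            float(cdf(x, (1, 0, 1))), abs=1e-10)


class TestQuantile:
    def test_round_trip_uniform_grid(self, theta_unit):
        p = np.linspace(0.001, 0.999, 199)
        assert np.max(np.abs(cdf(quantile(p, theta_unit), theta_unit) - p)) < 1e-8

    def test_round_trip_x(self, theta_unit):
        assert float(quantile(float(cdf(2.0, theta_unit)), theta_unit)) == \
            pytest.approx(2.0, abs=1e-9)

    def test_median_vs_bisection_oracle(self, theta_unit):
        root = optimize.brentq(lambda x: float(cdf(x, theta_unit)) - 0.5,
                               1e-6, 1e6, xtol=1e-12)
        assert float(quantile(0.5, theta_unit)) == pytest.approx(root, abs=1e-9)

    def test_strictly_increasing(self, random_thetas):
        p = np.linspace(0.01, 0.99, 25)
        for th in random_thetas[:30]:
            q = quantile(p, th)
            assert np.all(np.diff(q) > 0)

    def test_large_beta_stable(self):
        """wrightomega path stays finite where exp(beta) would overflow."""
        q = quantile(np.array([0.1, 0.9]), (1.0, 800.0, 2.0))
        assert np.all(np.isfinite(q)) and np.all(q > 0)


class TestSurvivalQuantities:
    def test_sf_complements_cdf(self, random_thetas):
        for th in random_thetas[:50]:
            x = th.alpha * 1.7
            assert float(sf(x, th) + cdf(x, th)) == pytest.approx(1.0, abs=1e-12)

    def test_hazard_identity(self, rng):
        """hazard * sf == pdf at random (x, theta)."""
        for _ in range(20):
            th = ParamVector(*rng.uniform(0.2, 4.0, 3))
            x = float(rng.uniform(0.1, 6.0))
            assert float(hazard(x, th) * sf(x, th)) == pytest.approx(
                float(pdf(x, th)), rel=1e-10)

    def test_hazard_closed_form_vs_ratio(self, theta_unit):
        """The exp(-beta F) cancellation: closed form equals pdf/sf."""
        for x in (0.2, 0.7, 1.5, 4.0):
            assert float(hazard(x, theta_unit)) == pytest.approx(
                float(pdf(x, theta_unit) / sf(x, theta_unit)), rel=1e-10)

    def test_cumulative_hazard_nondecreasing(self, theta_half):
        x = np.geomspace(0.01, 100.0, 80)
        ch = -logsf(x, theta_half)
        assert np.all(np.diff(ch) >= 0)

    def test_extreme_x_overflow_safe(self, theta_unit):
        """No NaN at extreme arguments; exact limits instead."""
        assert float(sf(1e-12, theta_unit)) == 1.0
        assert float(cdf(1e12, theta_unit)) == pytest.approx(1.0, abs=1e-11)
        assert float(cdf(1e300, theta_unit)) == 1.0
        for x in (1e-12, 1e12):
            assert not math.isnan(float(hazard(x, theta_unit)))
            assert not math.isnan(float(reversed_hazard(x, theta_unit)))

    def test_reversed_hazard_definition(self, theta_unit):
        x = 0.9
        assert float(reversed_hazard(x, theta_unit)) == pytest.approx(
            float(pdf(x, theta_unit) / cdf(x, theta_unit)), rel=1e-10)


class TestRandomVariates:
    def test_deterministic_under_seed(self, theta_unit):
        a = rvs(100, theta_unit, seed=5)
        b = rvs(100, theta_unit, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_empirical_cdf_close(self):
        """sup-distance of the ecdf of 50,000 draws below the DKW-style 0.012."""
        th = (0.5, 0.5, 0.5)
        x = np.sort(rvs(50_000, th, seed=99))
        ec = np.arange(1, x.size + 1) / x.size
        d = np.max(np.abs(ec - cdf(x, th)))
        assert d < 0.012

    def test_sample_median_matches_quantile(self):
        th = ParamVector(3.0, 3.0, 3.0)
        x = rvs(100_000, th, seed=17)
        med = float(np.median(x))
        assert med == pytest.approx(float(quantile(0.5, th)), rel=0.01)


class TestOrderStatistics:
    def test_single_observation_reduces(self, theta_unit):
        x = 1.3
        assert float(order_stat_pdf(1, 1, x, theta_unit)) == pytest.approx(
            float(pdf(x, theta_unit)))
        assert float(order_stat_cdf(1, 1, x, theta_unit)) == pytest.approx(
            float(cdf(x, theta_unit)))

    def test_cdf_vs_simulation_oracle(self, theta_unit):
        """P(X_(2:3) <= x) by Monte-Carlo frequency over simulated triples."""
        x0 = float(quantile(0.6, theta_unit))
        draws = rvs(3 * 200_000, theta_unit, seed=31).reshape(-1, 3)
        second = np.sort(draws, axis=1)[:, 1]
        freq = float(np.mean(second <= x0))
        assert float(order_stat_cdf(2, 3, x0, theta_unit)) == pytest.approx(
            freq, abs=3e-3)

    def test_exchangeability_mixture(self, theta_unit):
        """Mean over i of the order-statistic densities equals the density."""
        n = 5
        for x in (0.4, 1.0, 2.2):
            mix = np.mean([float(order_stat_pdf(i, n, x, theta_unit))
                           for i in range(1, n + 1)])
            assert mix == pytest.approx(float(pdf(x, theta_unit)), rel=1e-10)

    def test_out_of_range_raises(self, theta_unit):
        with pytest.raises(ValueError):
            order_stat_pdf(0, 3, 1.0, theta_unit)
        with pytest.raises(ValueError):
            order_stat_cdf(4, 3, 1.0, theta_unit)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    _params = dict(
        p=st.floats(0.02, 0.98),
        a=st.floats(0.2, 4.0),
        b=st.floats(0.0, 4.0),
        l=st.floats(0.3, 4.0),
    )

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(**_params)
    def test_quantile_round_trip_property(p, a, b, l):
        """cdf(quantile(p)) == p across the parameter space."""
        th = ParamVector(a, b, l)
        assert float(cdf(quantile(p, th), th)) == pytest.approx(p, abs=1e-8)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(**_params)
    def test_hazard_survival_density_identity_property(p, a, b, l):
        """hazard * sf == pdf at the p-quantile for any parameters."""
        th = ParamVector(a, b, l)
        x = float(quantile(p, th))
        assert float(hazard(x, th) * sf(x, th)) == pytest.approx(
            float(pdf(x, th)), rel=1e-9)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_inverse_rayleigh_special_case():
    """lam = 2 runs through the general code path unchanged (regression)."""
    th = ParamVector(1.5, 0.8, 2.0)
    x = np.array([0.5, 1.0, 2.0, 5.0])
    F = np.exp(-((1.5 / x) ** 2))
    expect = 1.0 - (1.0 - F) * np.exp(-0.8 * F)
    np.testing.assert_allclose(cdf(x, th), expect, rtol=1e-12)
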