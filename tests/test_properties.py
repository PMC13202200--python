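"""Moments, MGF, entropy and order statistics against quadrature oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, special

from rterd import (
    DomainError,
    OrderStatSpec,
    ParamSet,
    central_coefficients,
    mgf,
    moment_summary,
    order_stat_pdf,
    pdf,
    raw_moment_quadrature,
    raw_moment_series,
    renyi_entropy,
    renyi_entropy_series,
    shannon_entropy,
)
from conftest import TABLE1_PARAMS

# reference values for the five-row moments table: m1..m4, variance,
# raw-moment skewness and kurtosis coefficients (row 5 recomputed here;
# its shape coefficients as published elsewhere appear transposed)
TABLE1_EXPECTED = {
    (1.5, 2.5): (0.3718, 0.2036, 0.1331, 0.0964, 0.0654, 1.4489, -0.6758),
    (2.5, 1.5): (0.3028, 0.1491, 0.0917, 0.0639, 0.0574, 1.5924, -0.1264),
    (2.75, 0.25): (0.2945, 0.1453, 0.0903, 0.0637, 0.0586, 1.6304, 0.0166),
    (3.75, 1.25): (0.2355, 0.0980, 0.0538, 0.0347, 0.0426, 1.7535, 0.6079),
    (0.75, 3.25): (0.4415, 0.2617, 0.1788, 0.1330, 0.0669, 1.3355, -1.0585),
}


class TestRawMoments:
    @pytest.mark.parametrize("d,lam", TABLE1_PARAMS)
    def test_quadrature_matches_reference_table(self, d, lam):
        m1, m2, m3, m4, var, sc, kc = TABLE1_EXPECTED[(d, lam)]
        p = ParamSet(d, lam)
        for r, expected in zip((1, 2, 3, 4), (m1, m2, m3, m4)):
            assert raw_moment_quadrature(r, p) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("d,lam", TABLE1_PARAMS)
    def test_series_equals_quadrature(self, d, lam):
        p = ParamSet(d, lam)
        for r in (1, 2, 3, 4):
            assert raw_moment_series(r, p, tol=1e-13) == pytest.approx(
                raw_moment_quadrature(r, p), abs=1e-8)

    def test_small_lam_limit_is_truncated_exponential_moment(self):
        # only the i = 0 series term survives as lam -> 0:
        # E[X^r] -> gammainc(r+1, delta) / (delta^r * (1 - e^-delta))
        p = ParamSet(2.0, 1e-12)
        for r in (1, 2, 3):
            closed = (special.gammainc(r + 1, 2.0) * special.gamma(r + 1)
                      / (2.0 ** r * -math.expm1(-2.0)))
            assert raw_moment_series(r, p) == pytest.approx(closed, rel=1e-9)

    def test_moment_ordering(self, param_grid):
        for p in param_grid:
            ms = [raw_moment_quadrature(r, p) for r in (1, 2, 3, 4)]
            assert 0.0 < ms[3] < ms[2] < ms[1] < ms[0] < 1.0

    def test_invalid_order_rejected(self, std_params):
        with pytest.raises(DomainError):
            raw_moment_quadrature(0, std_params)
        with pytest.raises(DomainError):
            raw_moment_series(1, std_params, tol=-1.0)


class TestMomentSummary:
    @pytest.mark.parametrize("d,lam", TABLE1_PARAMS)
    def test_summary_matches_reference_table(self, d, lam):
        m1, m2, m3, m4, var, sc, kc = TABLE1_EXPECTED[(d, lam)]
        ms = moment_summary(ParamSet(d, lam))
        assert ms.variance == pytest.approx(var, abs=5e-5)
        assert ms.skew_coef == pytest.approx(sc, abs=2e-4)
        assert ms.kurt_coef == pytest.approx(kc, abs=2e-4)
        assert ms.variance == ms.m2 - ms.m1 ** 2

    def test_raw_coefficients_differ_from_central(self, std_params):
        ms = moment_summary(std_params)
        skew_c, kurt_c = central_coefficients(std_params)
        # the raw-moment ratios are a different statistic on purpose
        assert skew_c != pytest.approx(ms.skew_coef, abs=1e-3)
        assert abs(skew_c) < abs(ms.skew_coef)


class TestMGF:
    def test_at_zero_is_one(self, param_grid):
        for p in param_grid[::4]:
            assert mgf(0.0, p) == pytest.approx(1.0, abs=1e-10)

    def test_value_against_simpson_oracle(self, std_params):
        xs = np.linspace(0.0, 1.0, 2001)
        oracle = integrate.simpson(np.exp(xs) * pdf(xs, std_params), x=xs)
        assert mgf(1.0, std_params) == pytest.approx(oracle, abs=1e-7)
        assert mgf(1.0, std_params) == pytest.approx(1.5005, abs=5e-5)

    def test_series_matches_quadrature_where_valid(self, std_params):
        for t in (-1.0, -0.2, 0.3, 1.0, 1.4):
            assert mgf(t, std_params, method="series") == pytest.approx(
                mgf(t, std_params), abs=1e-8)

    def test_series_domain_error_beyond_delta(self, std_params):
        with pytest.raises(DomainError):
            mgf(1.5, std_params, method="series")

    def test_derivative_at_zero_is_mean(self, std_params):
        h = 1e-5
        deriv = (mgf(h, std_params) - mgf(-h, std_params)) / (2.0 * h)
        assert deriv == pytest.approx(raw_moment_quadrature(1, std_params), abs=1e-6)


class TestEntropy:
    def test_renyi_order_two(self, std_params):
        # oracle: Simpson quadrature of the squared density, then -log
        xs = np.linspace(0.0, 1.0, 2001)
        oracle = -math.log(integrate.simpson(pdf(xs, std_params) ** 2, x=xs))
        res = renyi_entropy(2.0, std_params)
        assert res.value == pytest.approx(oracle, abs=1e-6)
        assert res.value == pytest.approx(-0.182, abs=1e-3)

    def test_near_uniform_limit_entropy_vanishes(self):
        # tiny parameters make the density essentially uniform on [0, 1]
        p = ParamSet(1e-7, 1e-11)
        assert renyi_entropy(2.0, p).value == pytest.approx(0.0, abs=1e-6)

    def test_continuity_across_eta_one(self, std_params):
        sh = shannon_entropy(std_params)
        below = renyi_entropy(1.0 - 1e-4, std_params).value
        above = renyi_entropy(1.0 + 1e-4, std_params).value
        assert min(below, above) - 1e-3 <= sh <= max(below, above) + 1e-3

    def test_series_route_where_it_converges(self):
        p = ParamSet(2.5, 1.5)  # requires lam < delta
        assert renyi_entropy_series(2.0, p).value == pytest.approx(
            renyi_entropy(2.0, p).value, abs=1e-8)

    def test_series_route_rejected_outside_domain(self, std_params):
        with pytest.raises(DomainError):
            renyi_entropy_series(2.0, std_params)  # lam > delta

    @pytest.mark.parametrize("eta", [0.0, -1.0, 1.0])
    def test_invalid_order_rejected(self, std_params, eta):
        with pytest.raises(DomainError):
            renyi_entropy(eta, std_params)


class TestOrderStatistics:
    def test_single_observation_reduces_to_pdf(self, std_params):
        xs = np.linspace(0.0, 1.0, 101)
        spec = OrderStatSpec(K=1, P=1)
        np.testing.assert_allclose(order_stat_pdf(xs, spec, std_params),
                                   pdf(xs, std_params), atol=1e-14)

    def test_density_normalizes(self, std_params):
        spec = OrderStatSpec(K=5, P=3)
        total, _ = integrate.quad(lambda x: order_stat_pdf(x, spec, std_params),
                                  0.0, 1.0, epsabs=1e-12)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_rank_mixture_recovers_parent_density(self, std_params):
        # averaging over a uniformly random rank gives back the parent pdf
        K = 6
        xs = np.linspace(0.0, 1.0, 101)
        mix = sum(order_stat_pdf(xs, OrderStatSpec(K=K, P=P), std_params)
                  for P in range(1, K + 1)) / K
        np.testing.assert_allclose(mix, pdf(xs, std_params), atol=1e-10)

    def test_extreme_ranks_have_printed_closed_forms(self, std_params):
        # P=1 (minimum) and P=K (maximum) collapse to single-power forms
        K = 4
        xs = np.linspace(0.0, 1.0, 51)
        zf = std_params.Z
        h = std_params.delta * xs + 0.5 * std_params.lam * xs ** 2
        tail = math.exp(-(std_params.delta + 0.5 * std_params.lam))
        base = (std_params.delta + std_params.lam * xs) * np.exp(-h)
        g_min = K * (np.exp(-h) - tail) ** (K - 1) * base / zf ** K
        g_max = K * (-np.expm1(-h)) ** (K - 1) * base / zf ** K
        np.testing.assert_allclose(
            order_stat_pdf(xs, OrderStatSpec(K=K, P=1), std_params), g_min, atol=1e-12)
        np.testing.assert_allclose(
            order_stat_pdf(xs, OrderStatSpec(K=K, P=K), std_params), g_max, atol=1e-12)

    def test_invalid_rank_rejected(self):
        with pytest.raises(DomainError):
            OrderStatSpec(K=3, P=4)
        with pytest.raises(DomainError):
            OrderStatSpec(K=3, P=0)
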