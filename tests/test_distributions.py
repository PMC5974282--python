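"""Gauss-power and generalized-NB density correctness.

Oracles: the K = 0 closed form (normal(g, f) truncated to x > 0), an
independent arbitrary-precision re-coding of both formulas via mpmath-free
sympy evaluation, and brute-force fixed-grid quadrature.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gausspower.distributions import (GPParams, NBParams, gp_cdf_grid,
                                      gp_density, gp_density_unnormalized,
                                      gp_logpdf_unnorm, gp_normalize,
                                      gp_sample, gp_support_grid, nb_density,
                                      truncnorm_logpdf, truncnorm_mean)


def _gp_highprec(x, g, f, K):
    """Independent arbitrary-precision evaluation of the G-P formula."""
    import sympy as sp
    xs, gs, fs, Ks = [sp.Rational(str(v)) for v in (x, g, f, K)]
    expr = ((Ks + xs) / (fs * xs) * xs ** ((2 * gs * Ks - Ks ** 2) / fs ** 2)
            * sp.exp(-(gs * Ks ** 2 / xs + (2 * Ks - gs) * xs
                       + xs ** 2 / 2) / fs ** 2))
    return float(sp.N(expr, 50))


def _nb_highprec(x, s, k, Q):
    import sympy as sp
    xs, ss, ks, Qs = [sp.Rational(str(v)) for v in (x, s, k, Q)]
    expr = (sp.gamma(ss * xs + ks + 1) / (sp.gamma(ks) * sp.gamma(ss * xs + 1))
            * Qs ** ks * (1 - Qs) ** (ss * xs))
    return float(sp.N(expr, 50))


class TestGPDensity:
    def test_K0_collapses_to_exponential_quadratic(self):
        # (1/f) exp(gx/f^2 - x^2/2f^2) at x=g=f=1 is e^{1/2}
        val = gp_density_unnormalized(1.0, GPParams(1, 1, 0))
        assert val == pytest.approx(math.e ** 0.5, rel=1e-12)

    def test_vanishes_at_origin_for_positive_K(self):
        assert gp_density_unnormalized(1e-8, GPParams(1, 1, 1)) < 1e-100

    @pytest.mark.parametrize("x,g,f,K", [
        (2.0, 1.0, 3.0, 5.0), (0.5, 2.0, 0.5, 0.1), (7.0, 1.0, 30.0, 30.0),
    ])
    def test_matches_high_precision_oracle(self, x, g, f, K):
        ours = gp_density_unnormalized(x, GPParams(g, f, K))
        assert ours == pytest.approx(_gp_highprec(x, g, f, K), rel=1e-10)

    def test_domain_and_validation_errors(self):
        with pytest.raises(ValueError):
            gp_density_unnormalized(-1.0, GPParams(1, 1, 0))
        with pytest.raises(ValueError):
            GPParams(g=-1, f=1, K=0)
        with pytest.raises(ValueError):
            GPParams(g=1, f=0, K=0)
        with pytest.raises(ValueError):
            GPParams(g=1, f=1, K=float("nan"))


class TestNormalization:
    def test_K0_normalization_equals_truncated_normal(self):
        # A = exp(-g^2/2f^2) / (sqrt(2*pi) f Phi(g/f)) in closed form
        p = gp_normalize(GPParams(1, 1, 0))
        assert p.A == pytest.approx(0.28760, abs=5e-6)
        # phi(0) / Phi(g/f) at x = g: 0.3989423 / 0.8413447
        assert gp_density(1.0, p) == pytest.approx(0.4741722, abs=5e-6)

    @pytest.mark.parametrize("g,f", [(1, 1), (2, 0.5), (1, 10), (0.3, 2)])
    def test_gaussian_limit_pointwise(self, g, f):
        p = gp_normalize(GPParams(g, f, 0))
        xs = np.linspace(f * 1e-3, g + 8 * f, 100)
        ours = gp_density(xs, p)
        oracle = np.exp(truncnorm_logpdf(xs, g, f))
        assert np.allclose(ours, oracle, rtol=1e-8)

    @pytest.mark.parametrize("g,f,K", [
        (1, 1, 0), (1, 3, 5), (1, 30, 30), (1, 10, 10), (5, 0.5, 0.1),
    ])
    def test_unit_mass(self, g, f, K):
        p = gp_normalize(GPParams(g, f, K))
        x = gp_support_grid(p, n=1 << 16)
        mass = np.trapezoid(gp_density(x, p), x)
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_adaptive_quadrature_agrees_with_brute_force_trapezoid(self):
        p = gp_normalize(GPParams(1, 10, 10))
        x = gp_support_grid(p, n=10 ** 6)
        A_brute = 1.0 / np.trapezoid(
            np.exp(gp_logpdf_unnorm(x, p)), x)
        assert p.A == pytest.approx(A_brute, rel=1e-4)

    def test_power_regime_straight_line_on_interior_window(self):
        # K/g = f/g = 1e3: slope on the interior of (g, K) is constant;
        # near the edges the 1/x and linear terms bend it
        p = gp_normalize(GPParams(1, 1000, 1000))
        xs = np.geomspace(10, 50, 30)
        slopes = np.diff(np.log10(gp_density(xs, p))) / np.diff(np.log10(xs))
        assert np.all(np.abs(slopes / np.mean(slopes) - 1) < 0.05)
        assert np.mean(slopes) == pytest.approx(-2.0, abs=0.1)

    def test_tail_eventually_decreasing(self):
        p = gp_normalize(GPParams(1, 3, 5))
        xs = np.linspace(20, 80, 200)
        assert np.all(np.diff(gp_density(xs, p)) < 0)


class TestSampling:
    def test_truncated_normal_mean_recovered(self):
        p = gp_normalize(GPParams(1, 1, 0))
        s = gp_sample(p, 10 ** 5, seed=42)
        mu = truncnorm_mean(1, 1)
        se = s.std(ddof=1) / math.sqrt(len(s))
        assert abs(s.mean() - mu) < 3 * se

    def test_deterministic_given_seed(self):
        p = gp_normalize(GPParams(1, 3, 5))
        a = gp_sample(p, 1000, seed=7)
        b = gp_sample(p, 1000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_ks_distance_to_quadrature_cdf(self, gp_ks_oracle):
        p = gp_normalize(GPParams(1, 3, 5))
        s = gp_sample(p, 10 ** 5, seed=3)
        assert gp_ks_oracle(s, p) < 0.01

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            gp_sample(gp_normalize(GPParams(1, 1, 0)), 0, seed=1)


class TestNB:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.5), (1.0, 0.75)])
    def test_integer_gamma_closed_form(self, x, expected):
        assert nb_density(x, NBParams(1, 2, 0.5)) == pytest.approx(expected)

    def test_matches_high_precision_oracle(self):
        ours = nb_density(7.3, NBParams(0.5, 1.7, 0.3))
        assert ours == pytest.approx(_nb_highprec(7.3, 0.5, 1.7, 0.3),
                                     rel=1e-10)

    def test_printed_numerator_vs_textbook_variant(self):
        # at s=1 and integer x the printed form carries an extra (x+k)
        # factor relative to the textbook NB pmf numerator
        k, Q, x = 2.0, 0.5, 3.0
        printed = nb_density(x, NBParams(1, k, Q))
        textbook = nb_density(x, NBParams(1, k, Q, textbook_numerator=True))
        assert printed == pytest.approx((x + k) * textbook, rel=1e-12)

    def test_large_arguments_stay_finite(self):
        assert np.isfinite(nb_density(500.0, NBParams(1.0, 2.0, 0.01)))

    def test_validation(self):
        with pytest.raises(ValueError):
            NBParams(1, 2, 1.5)
        with pytest.raises(ValueError):
            nb_density(-1.0, NBParams(1, 2, 0.5))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(g=st.floats(0.1, 10), f=st.floats(0.1, 10), K=st.floats(0, 10))
def test_normalized_density_integrates_to_one(g, f, K):
    p = gp_normalize(GPParams(g, f, K))
    x, cdf = gp_cdf_grid(p)
    assert cdf[-1] == pytest.approx(1.0)
    # CDF monotone and the density nonnegative everywhere on the grid
    assert np.all(np.diff(cdf) >= 0)
    assert np.all(gp_density(x, p) >= 0)
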