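"""Closed-form density values, reductions, normalization and MRT calculus."""

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from gdctac import (
    GammaParams,
    GDCShape,
    InvalidParameterError,
    edc_density,
    gd_density,
    gdc_density,
    gdc_mrt,
    mrt_numeric,
)


class TestGammaDensity:
    @pytest.mark.parametrize(
        "shape,rate,tau,expected",
        [
            (1.0, 2.0, 0.0, 2.0),  # exponential at the origin
            (2.0, 1.0, 1.0, np.exp(-1.0)),
            (0.9, 0.003, -5.0, 0.0),  # zero before arrival
        ],
    )
    def test_values(self, shape, rate, tau, expected):
        assert gd_density(GammaParams(shape, rate), tau) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_scipy_gamma(self):
        p = GammaParams(0.8661, 0.004081)
        tau = np.linspace(0.1, 800, 50)
        np.testing.assert_allclose(
            gd_density(p, tau), stats.gamma.pdf(tau, a=p.shape, scale=1 / p.rate),
            rtol=1e-12,
        )

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            GammaParams(-1.0, 2.0)
        with pytest.raises(InvalidParameterError):
            GammaParams(1.0, 0.0)

    def test_origin_divergence_is_capped_with_warning(self):
        p = GammaParams(0.5, 1.0)
        with pytest.warns(RuntimeWarning):
            v = gd_density(p, 0.0)
        assert np.isfinite(v)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        shape=st.floats(0.05, 0.999),
        rate=st.floats(1e-4, 10.0),
    )
    def test_washout_shape_is_monotone_decreasing(self, shape, rate):
        """shape < 1 guarantees a strictly decreasing washout curve."""
        p = GammaParams(shape, rate)
        tau = np.linspace(0.01, 10.0 / rate, 200)
        vals = gd_density(p, tau)
        assert np.all(np.diff(vals) < 0)


class TestBatemanDensity:
    def test_distinct_rates(self):
        # b*beta*(e^-beta - e^-b)/(b-beta) at t=1
        assert edc_density(1.0, 0.5, 1.0) == pytest.approx(
            np.exp(-0.5) - np.exp(-1.0), rel=1e-12
        )

    def test_equal_rates_limit(self):
        assert edc_density(1.0, 1.0, 1.0) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_zero_initial_height(self):
        assert edc_density(3.0, 0.2, 0.0) == 0.0

    def test_branch_switch_is_continuous(self):
        t = 2.3
        base = edc_density(1.0, 1.0, t)
        for eps in (1e-9, 1e-10, 1e-12):
            assert edc_density(1.0, 1.0 + eps, t) == pytest.approx(base, rel=1e-6)

    def test_invalid_rates_raise(self):
        with pytest.raises(InvalidParameterError):
            edc_density(0.0, 1.0, 1.0)


class TestGDCDensity:
    def test_zero_at_and_before_origin(self):
        s = GDCShape.from_values(3.7, 5.2, 0.87, 0.004)
        assert gdc_density(s, 0.0) == 0.0
        assert gdc_density(s, -1.0) == 0.0

    def test_reduces_to_bateman_for_unit_shapes(self):
        """a = alpha = 1 collapses the convolution to the Bateman density."""
        for b, beta in [(1.0, 0.5), (5.2, 0.004), (2.0, 1.9)]:
            s = GDCShape.from_values(1.0, b, 1.0, beta)
            tau = np.geomspace(1e-3, 100.0, 60)
            np.testing.assert_allclose(
                gdc_density(s, tau), edc_density(b, beta, tau), rtol=1e-10
            )

    def test_reduces_to_single_gamma_for_equal_rates(self):
        """b = beta collapses to GD(a + alpha, b)."""
        s = GDCShape.from_values(1.5, 2.0, 0.5, 2.0)
        assert gdc_density(s, 1.0) == pytest.approx(4.0 * np.exp(-2.0), rel=1e-12)
        tau = np.geomspace(1e-3, 50.0, 60)
        np.testing.assert_allclose(
            gdc_density(s, tau),
            gd_density(GammaParams(2.0, 2.0), tau),
            rtol=1e-10,
        )

    def test_agrees_with_arbitrary_precision_hypergeometric(self, case_list):
        """scipy's 1F1 path matches an mpmath evaluation of the printed form."""
        for case in case_list[:3]:
            s = case.params.shape
            for tau in (0.3, 1.0, 10.0, 89.0, 500.0):
                ref = float(
                    mp.mpf(s.b) ** s.a
                    * mp.mpf(s.beta) ** s.alpha
                    / mp.gamma(s.a + s.alpha)
                    * mp.e ** (-s.b * tau)
                    * mp.mpf(tau) ** (s.a + s.alpha - 1)
                    * mp.hyp1f1(s.alpha, s.a + s.alpha, (s.b - s.beta) * tau)
                )
                assert gdc_density(s, tau) == pytest.approx(ref, rel=1e-10)

    def test_finite_and_nonnegative_far_into_the_tail(self, case_list):
        for case in case_list:
            s = case.params.shape
            tau = np.linspace(0.01, 10.0 * s.alpha / s.beta, 300)
            vals = gdc_density(s, tau)
            assert np.all(np.isfinite(vals))
            assert np.all(vals >= 0)

    def test_normalization_of_clinical_shapes(self, case_list):
        for case in case_list:
            s = case.params.shape
            area = integrate.quad(
                lambda t: gdc_density(s, t), 0, np.inf, limit=200
            )[0]
            assert area == pytest.approx(1.0, abs=1e-6)

    def test_tail_converges_to_washout_component(self, case_list):
        """Far from the peak the convolution tracks the washout gamma alone."""
        for case in case_list:
            s = case.params.shape
            ratio = gdc_density(s, 500.0) / gd_density(s.washout, 500.0)
            assert ratio == pytest.approx(1.0, abs=0.01)


class TestMRT:
    def test_printed_clinical_mrts(self, cases):
        m = gdc_mrt(cases["1R"].params.shape)
        assert m.mrt_fast == pytest.approx(0.716, abs=2e-3)
        assert m.mrt_wo == pytest.approx(212.2, abs=0.15)

    def test_unit_ratios(self):
        m = gdc_mrt(GDCShape.from_values(1, 1, 1, 1), t_A=0.0)
        assert (m.mrt_fast, m.mrt_wo, m.mrt_total_from_injection) == (1.0, 1.0, 2.0)

    def test_arrival_offset_adds_but_is_not_organ_residence(self):
        s = GDCShape.from_values(2.0, 3.0, 0.9, 0.01)
        m = gdc_mrt(s, t_A=0.4)
        assert m.mrt_total_from_injection == pytest.approx(0.4 + 2 / 3 + 90.0)
        assert m.mrt_organ == pytest.approx(2 / 3 + 90.0)

    def test_additivity_matches_quadrature(self):
        """First moment of the convolution equals a/b + alpha/beta."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            s = GDCShape.from_values(
                rng.uniform(0.6, 8.0),
                rng.uniform(0.8, 12.0),
                rng.uniform(0.5, 0.99),
                rng.uniform(1e-3, 6e-3),
            )
            target = s.a / s.b + s.alpha / s.beta
            assert mrt_numeric(lambda t: gdc_density(s, t)) == pytest.approx(
                target, rel=1e-6
            )

    def test_numeric_moment_examples(self, cases):
        assert mrt_numeric(
            lambda t: 0.5 * np.exp(-0.5 * np.asarray(t))
        ) == pytest.approx(2.0, rel=1e-9)
        p = GammaParams(0.8661, 0.004081)
        assert mrt_numeric(lambda t: gd_density(p, t)) == pytest.approx(
            212.23, abs=0.01
        )
        s = cases["2T"].params.shape
        assert mrt_numeric(lambda t: gdc_density(s, t)) == pytest.approx(
            0.937 + 339.3, abs=0.1
        )

    def test_non_normalized_density_rejected(self):
        with pytest.raises(ValueError):
            mrt_numeric(lambda t: np.exp(-0.5 * np.asarray(t)))  # area = 2

    def test_negative_arrival_rejected(self):
        with pytest.raises(InvalidParameterError):
            gdc_mrt(GDCShape.from_values(1, 1, 0.9, 0.01), t_A=-0.1)
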