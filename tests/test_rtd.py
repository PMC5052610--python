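"""RTD analysis: normalization, moments, dead space, model fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aobr import (CCurve, NormalizedCurve, ReactorConfig, TracerExperiment,
                  classify_mixing, curve_moments, dead_space_fraction,
                  fit_dispersion, fit_tanks_in_series, measured_hrt,
                  normalize_curve, simulate_tracer_pulse, summarize_rtd)
from aobr.errors import (ConfigError, InsufficientHorizonError,
                         UndefinedMomentsError)

from conftest import dense_experiment, erlang_curve, gaussian_pulse_curve


class TestNormalization:
    def test_theta_and_c_theta_definitions(self, simple_ccurve):
        norm = normalize_curve(simple_ccurve)
        np.testing.assert_allclose(norm.theta, simple_ccurve.times / 48.0)
        assert norm.theta[-1] == pytest.approx(3.0)  # 144 h at HRT 48 h
        # C equal to c0 maps to C_theta = 1
        flat = CCurve(times=np.array([0.0, 24.0, 48.0]),
                      concentrations=np.array([2.0, 2.0, 2.0]),
                      c0=2.0, nominal_hrt=48.0)
        np.testing.assert_allclose(normalize_curve(flat).c_theta, 1.0)

    def test_invalid_reference_values_rejected(self, simple_ccurve):
        simple_ccurve.c0 = 0.0
        with pytest.raises(ConfigError):
            normalize_curve(simple_ccurve)


class TestMoments:
    def test_exponential_curve_has_unit_mean_and_variance(self, cstr_curve):
        mean, var = curve_moments(cstr_curve)
        assert mean == pytest.approx(1.0, abs=1e-3)
        assert var == pytest.approx(1.0, abs=1e-3)

    def test_erlang4_variance_is_one_quarter(self):
        _, var = curve_moments(erlang_curve(4))
        assert var == pytest.approx(0.25, abs=1e-3)

    def test_discrete_curve_matches_hand_quadrature(self):
        """Five-point curve against an explicit trapezoid hand-summation."""
        theta = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
        c = np.array([0.0, 1.2, 0.8, 0.3, 0.1])
        area = m1 = 0.0
        for i in range(4):
            h = theta[i + 1] - theta[i]
            area += 0.5 * h * (c[i] + c[i + 1])
            m1 += 0.5 * h * (theta[i] * c[i] + theta[i + 1] * c[i + 1])
        mean_oracle = m1 / area
        m2 = 0.0
        for i in range(4):
            h = theta[i + 1] - theta[i]
            m2 += 0.5 * h * ((theta[i] - mean_oracle) ** 2 * c[i]
                             + (theta[i + 1] - mean_oracle) ** 2 * c[i + 1])
        var_oracle = m2 / area
        mean, var = curve_moments(NormalizedCurve(theta=theta, c_theta=c))
        assert mean == pytest.approx(mean_oracle, abs=1e-12)
        assert var == pytest.approx(var_oracle, abs=1e-12)

    def test_degenerate_curves_raise(self):
        flatzero = NormalizedCurve(theta=np.linspace(0, 3, 10),
                                   c_theta=np.zeros(10))
        with pytest.raises(UndefinedMomentsError):
            curve_moments(flatzero)
        with pytest.raises(UndefinedMomentsError):
            curve_moments(NormalizedCurve(theta=np.array([0.0, 1.0]),
                                          c_theta=np.array([1.0, 1.0])))


class TestMeasuredHRT:
    def test_ideal_cstr_returns_nominal(self, cstr_curve):
        assert measured_hrt(cstr_curve, 48.0) == pytest.approx(48.0, abs=0.05)

    def test_early_centroid_scales_down(self):
        """A curve whose computed centroid is 0.929 gives 44.6 h at 48 h."""
        curve = gaussian_pulse_curve(center=0.929)
        mean, _ = curve_moments(curve)
        assert mean == pytest.approx(0.929, abs=1e-3)
        assert measured_hrt(curve, 48.0) == pytest.approx(44.6, abs=0.1)

    def test_symmetric_pulse_at_unity(self):
        assert measured_hrt(gaussian_pulse_curve(center=1.0), 48.0) == \
            pytest.approx(48.0, abs=0.05)


class TestDeadSpace:
    def test_plug_flow_pulse_has_no_dead_space(self):
        assert dead_space_fraction(gaussian_pulse_curve(center=1.0, width=0.01)) \
            == pytest.approx(0.0, abs=1e-6)

    def test_ideal_cstr_analytic_value(self, cstr_curve):
        """1 - (1 - 3 e^-2)/(1 - e^-2) for e^-theta truncated at theta = 2."""
        expected = 1.0 - (1.0 - 3.0 * math.exp(-2)) / (1.0 - math.exp(-2))
        assert dead_space_fraction(cstr_curve) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.313, abs=5e-4)

    def test_simulated_single_tank_reactor_near_one_third(self):
        cfg = ReactorConfig(n_compartments=1, feed_split=(1.0,))
        curve = simulate_tracer_pulse(cfg, dense_experiment(3.0, 0.5))
        ds = dead_space_fraction(normalize_curve(curve))
        assert 0.28 < ds < 0.35

    def test_short_horizon_raises(self):
        short = gaussian_pulse_curve(center=0.5, upper=1.5)
        with pytest.raises(InsufficientHorizonError):
            dead_space_fraction(short)

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_concentration_rescaling(self, scale):
        theta = np.linspace(0, 3, 301)
        c = np.exp(-theta) * (1 + 0.3 * np.sin(4 * theta))
        base = dead_space_fraction(NormalizedCurve(theta=theta, c_theta=c))
        scaled = dead_space_fraction(NormalizedCurve(theta=theta, c_theta=scale * c))
        assert scaled == pytest.approx(base, rel=1e-9)


class TestModelFits:
    @pytest.mark.parametrize("variance, printed", [(0.28, 3.58), (0.30, 3.34)])
    def test_tanks_in_series_matches_printed_values(self, variance, printed):
        assert fit_tanks_in_series(variance) == pytest.approx(printed, rel=0.005)

    def test_unit_variance_is_single_tank(self):
        assert fit_tanks_in_series(1.0) == 1.0
        assert fit_tanks_in_series(1.5) == 1.0  # clamped below at 1

    @pytest.mark.parametrize("variance, expected", [(0.28, 0.14), (0.30, 0.15)])
    def test_small_dispersion_closed_form(self, variance, expected):
        assert fit_dispersion(variance) == pytest.approx(expected, abs=1e-12)

    def test_closed_vessel_round_trip(self):
        """Forward-evaluate sigma^2 at d = 0.14, then invert."""
        d = 0.14
        var = 2 * d - 2 * d**2 * (1 - math.exp(-1 / d))
        assert var == pytest.approx(0.2408, abs=5e-4)
        assert fit_dispersion(var, method="closed-vessel") == \
            pytest.approx(d, abs=1e-8)

    def test_closed_vessel_needs_variance_below_one(self):
        with pytest.raises(ConfigError):
            fit_dispersion(1.0, method="closed-vessel")

    def test_fits_increase_with_variance_and_agree_when_small(self):
        variances = np.linspace(0.005, 0.95, 40)
        small = [fit_dispersion(v) for v in variances]
        closed = [fit_dispersion(v, method="closed-vessel") for v in variances]
        assert np.all(np.diff(small) > 0)
        assert np.all(np.diff(closed) > 0)
        for v in (0.02, 0.05, 0.1):
            a, b = fit_dispersion(v), fit_dispersion(v, method="closed-vessel")
            assert abs(a - b) / b < 0.10

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ConfigError):
            fit_tanks_in_series(0.0)
        with pytest.raises(ConfigError):
            fit_dispersion(-0.1)


class TestClassification:
    @pytest.mark.parametrize("d, expected", [
        (0.33, "completely-mixed"),
        (0.14, "intermediate"),
        (0.15, "intermediate"),
        (0.01, "plug-flow"),
        (0.02, "intermediate"),  # boundaries count as intermediate
        (0.2, "intermediate"),
    ])
    def test_thresholds(self, d, expected):
        assert classify_mixing(d) == expected

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigError):
            classify_mixing(-0.01)


class TestSummary:
    def test_single_tank_summary(self):
        cfg = ReactorConfig(n_compartments=1, feed_split=(1.0,))
        curve = simulate_tracer_pulse(cfg, dense_experiment(10.0, 0.5))
        s = summarize_rtd(curve)
        assert s.mixing_class == "completely-mixed"
        assert s.n_tanks == pytest.approx(1.0, abs=0.02)
        assert s.dead_space_fraction == pytest.approx(0.31, abs=0.02)

    def test_summary_is_internally_consistent_and_deterministic(self, split_631_config):
        curve = simulate_tracer_pulse(split_631_config, dense_experiment(6.0, 1.0))
        a = summarize_rtd(curve)
        b = summarize_rtd(curve)
        assert a == b  # bit-identical, no hidden state
        assert a.n_tanks == pytest.approx(1.0 / a.variance_theta, rel=1e-12)
        assert a.dispersion_number == pytest.approx(a.variance_theta / 2, rel=1e-12)
        assert a.peclet * a.dispersion_number == pytest.approx(1.0, rel=1e-12)
        assert a.measured_hrt == pytest.approx(a.mean_theta * 48.32432, rel=1e-4)

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_tank_number_recovery_from_simulation(self, n):
        """Noise-free N-equal-tank simulation recovers N via the RTD chain."""
        cfg = ReactorConfig(n_compartments=n,
                            feed_split=(1.0,) + (0.0,) * (n - 1))
        curve = simulate_tracer_pulse(cfg, dense_experiment(12.0, 0.5))
        s = summarize_rtd(curve)
        assert s.n_tanks == pytest.approx(n, rel=0.02)
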