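import numpy as np
import pytest

from circust.fmm import (FMMParameters, cosinor_fit, fmm_evaluate, fmm_fit,
                         peak_time)

TWO_PI = 2 * np.pi


def _circ_diff(a, b):
    return np.abs(np.mod(a - b + np.pi, TWO_PI) - np.pi)


class TestEvaluate:
    def test_zero_amplitude_is_constant(self):
        p = FMMParameters(m=1.7, a=0.0, alpha=2.0, beta=1.0, omega=0.4)
        t = np.linspace(0, TWO_PI, 17, endpoint=False)
        np.testing.assert_allclose(fmm_evaluate(p, t), 1.7)

    def test_omega_one_reduces_to_sinusoid(self):
        # at omega = 1 the Mobius warp is the identity:
        # mu(t) = M + A cos(t + beta - alpha) to machine precision
        p = FMMParameters(m=0.5, a=2.0, alpha=0.9, beta=2.3, omega=1.0)
        t = np.linspace(0, TWO_PI, 1000, endpoint=False)
        expected = 0.5 + 2.0 * np.cos(t + 2.3 - 0.9)
        np.testing.assert_allclose(fmm_evaluate(p, t), expected, atol=1e-10)

    def test_value_against_high_precision_oracle(self):
        # independent 50-digit evaluation of the wave formula with sympy
        import sympy as sp
        M, A, alpha, beta, omega, t = 0, 1, 1, 2, sp.Rational(3, 10), 0
        psi = 2 * sp.atan(omega * sp.tan(sp.Rational(t - alpha, 2)))
        expected = float((M + A * sp.cos(beta + psi)).evalf(50))
        p = FMMParameters(m=0, a=1, alpha=1, beta=2, omega=0.3)
        assert fmm_evaluate(p, np.array([0.0]))[0] == pytest.approx(
            expected, abs=1e-12)

    def test_singularity_limit(self):
        # at t - alpha = pi the warp tends to pi: mu = M + A cos(beta + pi)
        p = FMMParameters(m=0.2, a=1.5, alpha=1.0, beta=0.7, omega=0.3)
        val = fmm_evaluate(p, np.array([1.0 + np.pi]))[0]
        assert val == pytest.approx(0.2 + 1.5 * np.cos(0.7 + np.pi), abs=1e-12)


class TestPeakTime:
    def test_cosine_peaks_at_zero(self):
        p = FMMParameters(m=0, a=1, alpha=0, beta=0, omega=1)
        assert peak_time(p) == pytest.approx(0.0, abs=1e-12)

    def test_translation_equivariance(self, rng):
        p = FMMParameters(m=0, a=1, alpha=1.2, beta=2.5, omega=0.4)
        for delta in rng.uniform(0, TWO_PI, 10):
            shifted = FMMParameters(m=0, a=1, alpha=1.2 + delta, beta=2.5,
                                    omega=0.4)
            assert _circ_diff(peak_time(shifted),
                              peak_time(p) + delta) < 1e-12

    def test_matches_dense_grid_argmax(self):
        p = FMMParameters(m=0, a=1, alpha=1, beta=2, omega=0.3)
        grid = np.linspace(0, TWO_PI, 100_000, endpoint=False)
        t_grid = grid[np.argmax(fmm_evaluate(p, grid))]
        assert _circ_diff(peak_time(p), t_grid) < 1e-3

    def test_flat_signal_raises(self):
        p = FMMParameters(m=0, a=0, alpha=0, beta=0, omega=1)
        with pytest.raises(ValueError, match="peak undefined"):
            peak_time(p)


class TestCosinorFit:
    def test_exact_recovery(self):
        t = np.linspace(0, TWO_PI, 12, endpoint=False)
        y = 2 + 3 * np.cos(t - 1)
        fit = cosinor_fit(y, t)
        assert fit.params.m == pytest.approx(2.0, abs=1e-10)
        assert fit.params.a == pytest.approx(3.0, abs=1e-10)
        assert _circ_diff(fit.t_u, 1.0) < 1e-10
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_pure_sine_peak(self):
        t = np.linspace(0, TWO_PI, 16, endpoint=False)
        fit = cosinor_fit(np.sin(t), t)
        assert _circ_diff(fit.t_u, np.pi / 2) < 1e-10

    def test_four_point_cosine(self):
        # y = (1, 0, -1, 0) at quadrant angles is exactly cos(t)
        t = np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        fit = cosinor_fit(np.array([1.0, 0.0, -1.0, 0.0]), t)
        assert fit.r2 >= 0.999
        assert _circ_diff(fit.t_u, 0.0) < 1e-8

    def test_constant_input(self):
        t = np.linspace(0, TWO_PI, 8, endpoint=False)
        fit = cosinor_fit(np.full(8, 2.0), t)
        assert fit.params.a == 0.0 and fit.r2 == 0.0


class TestFMMFit:
    def test_noise_free_recovery(self):
        true = FMMParameters(m=0.3, a=1.5, alpha=2.0, beta=4.0, omega=0.35)
        t = np.linspace(0, TWO_PI, 50, endpoint=False)
        fit = fmm_fit(fmm_evaluate(true, t), t)
        assert fit.r2 >= 0.999
        assert _circ_diff(fit.params.alpha, true.alpha) < 0.05
        assert _circ_diff(fit.params.beta, true.beta) < 0.05
        assert abs(fit.params.omega - true.omega) < 0.05

    def test_nesting_inequality(self, rng):
        t = np.sort(rng.uniform(0, TWO_PI, 40))
        for _ in range(5):
            y = rng.normal(size=40)
            assert fmm_fit(y, t).r2 >= cosinor_fit(y, t).r2

    def test_asymmetric_data_beats_cosinor(self):
        true = FMMParameters(m=0, a=1, alpha=1.0, beta=2.0, omega=0.2)
        t = np.linspace(0, TWO_PI, 60, endpoint=False)
        y = fmm_evaluate(true, t)
        assert fmm_fit(y, t).r2 > cosinor_fit(y, t).r2 + 0.05

    def test_shape_invariance_under_affine_response(self, rng):
        true = FMMParameters(m=0.1, a=1.2, alpha=2.5, beta=5.0, omega=0.5)
        t = np.linspace(0, TWO_PI, 48, endpoint=False)
        y = fmm_evaluate(true, t) + 0.05 * rng.normal(size=48)
        base = fmm_fit(y, t)
        scaled = fmm_fit(3.0 * y + 7.0, t)
        assert scaled.params.m == pytest.approx(3 * base.params.m + 7, abs=1e-4)
        assert scaled.params.a == pytest.approx(3 * base.params.a, rel=1e-4)
        assert abs(scaled.params.omega - base.params.omega) < 1e-4
        assert scaled.r2 == pytest.approx(base.r2, abs=1e-9)

    def test_r2_bounds_and_flat_input(self):
        t = np.linspace(0, TWO_PI, 10, endpoint=False)
        fit = fmm_fit(np.full(10, 1.0), t)
        assert fit.params.a == 0.0 and fit.r2 == 0.0
        with pytest.raises(ValueError, match="at least 7"):
            fmm_fit(np.arange(5.0), t[:5])

    def test_peak_matches_fitted_curve_argmax(self, rng):
        t = np.linspace(0, TWO_PI, 40, endpoint=False)
        y = np.cos(t - 1.3) + 0.1 * rng.normal(size=40)
        fit = fmm_fit(y, t)
        grid = np.linspace(0, TWO_PI, 100_000, endpoint=False)
        t_grid = grid[np.argmax(fmm_evaluate(fit.params, grid))]
        assert _circ_diff(fit.t_u, t_grid) < 1e-3
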