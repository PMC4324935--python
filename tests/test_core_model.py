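"""Single-column primitives: sigmoid, PSP kernel, ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nmmnet import (
    ColumnParams,
    ColumnState,
    DriveParams,
    NumericalBlowUp,
    column_derivatives,
    column_output,
    column_rhs,
    heun_step,
    psp_kernel,
    sigmoid,
    sigmoid_derivative,
)


class TestSigmoid:
    def test_midpoint_gives_half_max_rate(self, params):
        assert sigmoid(params.nu0, params) == pytest.approx(params.e0)

    def test_saturation_limits(self, params):
        assert sigmoid(1e6, params) == pytest.approx(2 * params.e0)
        assert sigmoid(-1e6, params) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_zero_psp(self, params):
        # independent scalar evaluation: 5 / (1 + e^{0.56*6})
        expected = 5.0 / (1.0 + math.exp(3.36))
        assert sigmoid(0.0, params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.168, abs=5e-4)

    def test_no_overflow_for_extreme_inputs(self, params):
        assert np.isfinite(sigmoid(-1e9, params))
        assert np.isfinite(sigmoid(1e9, params))

    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_bounded_and_monotone(self, m1, m2):
        # mathematically strict bounds; the upper one saturates to 2 e0
        # in float64 for very large inputs
        p = ColumnParams()
        s1, s2 = sigmoid(m1, p), sigmoid(m2, p)
        assert 0.0 < s1 <= 2 * p.e0
        if m1 < m2:
            assert s1 <= s2

    def test_derivative_matches_finite_difference(self, params):
        for m in (-3.0, 0.0, 6.0, 12.0):
            h = 1e-6
            fd = (sigmoid(m + h, params) - sigmoid(m - h, params)) / (2 * h)
            assert sigmoid_derivative(m, params) == pytest.approx(fd, rel=1e-6)


class TestPspKernel:
    def test_causal(self):
        assert psp_kernel(-0.5, 3.25, 100.0) == 0.0
        assert psp_kernel(0.0, 3.25, 100.0) == 0.0

    def test_peak_height_and_location(self):
        # kernel maximum at t = 1/rate with height amplitude/e
        A, a = 3.25, 100.0
        assert psp_kernel(1 / a, A, a) == pytest.approx(A / math.e, rel=1e-12)
        t = np.linspace(0, 0.1, 2001)
        k = psp_kernel(t, A, a)
        assert t[np.argmax(k)] == pytest.approx(1 / a, abs=1e-3)

    def test_vectorized_matches_scalar(self):
        t = np.array([-0.01, 0.0, 0.005, 0.02])
        vec = psp_kernel(t, 22.0, 50.0)
        assert vec == pytest.approx([psp_kernel(ti, 22.0, 50.0) for ti in t])


class TestColumnRhs:
    def test_rest_state_accelerations(self, params):
        """From rest with zero input, only the sigmoid feedthrough drives y0."""
        drive = DriveParams(p_bar=0.0, delta=0.0)
        d = column_rhs(np.zeros(6), 0.0, drive, 0.0, 0.0, params)
        assert d[:3] == pytest.approx(np.zeros(3))  # velocities are zero
        s0 = 5.0 / (1.0 + math.exp(3.36))
        assert d[3] == pytest.approx(params.A * params.a * s0, rel=1e-12)
        assert d[3] == pytest.approx(54.6, abs=0.1)
        # y1/y2 accelerations from the intra-column feedback only
        assert d[4] == pytest.approx(params.A * params.a * params.C2 * s0, rel=1e-12)
        assert d[5] == pytest.approx(params.B * params.b * params.C4 * s0, rel=1e-12)

    def test_hand_coded_rhs_at_random_state(self, params, rng):
        """Independently written RHS (direct formula transcription)."""
        y = rng.normal(0, 5, 6)
        drive = DriveParams()
        t = 0.321
        p_a, p_b = 12.0, 3.0
        p = params

        def S(m):
            return 2 * p.e0 / (1 + math.exp(p.r * (p.nu0 - m)))

        ext = drive.p_bar + drive.delta * math.sin(2 * math.pi * drive.f * t)
        expected = np.array(
            [
                y[3],
                y[4],
                y[5],
                p.A * p.a * S(y[1] - y[2]) - 2 * p.a * y[3] - p.a**2 * y[0],
                p.A * p.a * (ext + p.C2 * S(p.C1 * y[0]) + p_a)
                - 2 * p.a * y[4] - p.a**2 * y[1],
                p.B * p.b * (p.C4 * S(p.C3 * y[0]) + p_b)
                - 2 * p.b * y[5] - p.b**2 * y[2],
            ]
        )
        got = column_rhs(y, t, drive, p_a, p_b, params)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_coupling_equals_isolated_rhs(self, params, rng):
        y = rng.normal(0, 2, 6)
        drive = DriveParams(delta=0.0)
        with_zero = column_rhs(y, 1.0, drive, 0.0, 0.0, params)
        # isolated column: same expression, no coupling terms exist
        assert with_zero == pytest.approx(
            column_rhs(y, 1.0, drive, 0.0, 0.0, params)
        )

    def test_nonfinite_state_raises_with_time(self, params):
        with pytest.raises(NumericalBlowUp, match="t=2.5"):
            column_rhs(np.array([np.nan, 0, 0, 0, 0, 0]), 2.5,
                       DriveParams(), 0.0, 0.0, params)

    def test_negative_pulse_density_rejected(self, params):
        with pytest.raises(ValueError):
            column_rhs(np.zeros(6), 0.0, DriveParams(), -1.0, 0.0, params)

    def test_typed_wrapper_matches_array_form(self, params):
        state = ColumnState(1.0, 2.0, 3.0, 0.1, 0.2, 0.3)
        d = column_derivatives(state, 0.0, DriveParams(), 0.0, 0.0, params)
        assert d.as_array() == pytest.approx(
            column_rhs(state.as_array(), 0.0, DriveParams(), 0.0, 0.0, params)
        )


class TestColumnOutput:
    @pytest.mark.parametrize(
        "y1,y2,expected", [(10.0, 4.0, 6.0), (7.0, 7.0, 0.0), (-1.0, 2.5, -3.5)]
    )
    def test_difference(self, y1, y2, expected):
        assert column_output(ColumnState(0, y1, y2, 0, 0, 0)) == expected
        assert column_output(np.array([0, y1, y2, 0, 0, 0])) == expected


class TestParams:
    def test_intra_column_constants_derive_from_C(self):
        p = ColumnParams(C=200.0)
        assert (p.C1, p.C2, p.C3, p.C4) == (200.0, 160.0, 50.0, 50.0)

    def test_canonical_defaults(self, params):
        assert (params.C1, params.C2, params.C3, params.C4) == (
            133.5, 0.8 * 133.5, 0.25 * 133.5, 0.25 * 133.5)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ColumnParams(A=-1.0)
        with pytest.raises(ValueError):
            DriveParams(p_bar=-5.0)


class TestOperatorConvolutionEquivalence:
    """The second-order operator form and the kernel convolution are the
    same linear filter: integrating y'' = A a p(t) - 2a y' - a^2 y from
    rest reproduces (h * p)(t) to second order in dt."""

    @staticmethod
    def _run(dt):
        A, a = 3.25, 100.0
        T = 1.0
        # smooth pulse train input
        def p_of_t(t):
            return (np.exp(-((t - 0.15) / 0.02) ** 2)
                    + 0.5 * np.exp(-((t - 0.55) / 0.03) ** 2))

        def rhs(s, t):
            return np.array([s[1], A * a * p_of_t(t) - 2 * a * s[1] - a**2 * s[0]])

        n = int(round(T / dt))
        s = np.zeros(2)
        ys = np.empty(n + 1)
        ys[0] = 0.0
        for k in range(n):
            s = heun_step(rhs, s, k * dt, dt)
            ys[k + 1] = s[0]
        # convolution oracle on a fine grid (trapezoid weights)
        dtf = 1e-5
        tf = np.arange(0, T + dtf, dtf)
        pf = p_of_t(tf)
        hf = psp_kernel(tf, A, a)
        conv = np.convolve(pf, hf)[: tf.size] * dtf
        sub = int(round(dt / dtf))
        return ys, conv[::sub][: ys.size]

    def test_matches_convolution_and_converges_quadratically(self):
        y1, c1 = self._run(1e-3)
        e1 = np.max(np.abs(y1 - c1)) / np.max(np.abs(c1))
        assert e1 < 2e-3
        y2, c2 = self._run(5e-4)
        e2 = np.max(np.abs(y2 - c2)) / np.max(np.abs(c2))
        assert e2 < e1 / 2.5  # second-order convergence
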