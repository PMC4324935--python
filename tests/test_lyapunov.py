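"""Lyapunov machinery: Jacobian correctness, QR spectra, Benettin MLE."""

import numpy as np
import pytest

from nmmnet import (
    ColumnParams,
    CouplingParams,
    DriveParams,
    SimulationConfig,
    benettin_mle_generic,
    column_rhs,
    generate_barabasi_albert,
    lyapunov_spectrum,
    lyapunov_spectrum_generic,
    mle_map,
    system_jacobian,
)
from nmmnet.simulate import single_node_topology

SHORT_LYAP = SimulationConfig(t_total=60.0, t_transient=20.0, method="adams_bashforth")


def lorenz_rhs(s, t, sigma=10.0, rho=28.0, beta=8.0 / 3.0):
    x, y, z = s
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def lorenz_jac(s, t, sigma=10.0, rho=28.0, beta=8.0 / 3.0):
    x, y, z = s
    return np.array(
        [[-sigma, sigma, 0.0], [rho - z, -1.0, -x], [y, x, -beta]]
    )


class TestSystemJacobian:
    def test_matches_central_differences(self, rng):
        """Analytic Jacobian vs finite differences on a coupled network."""
        topo = generate_barabasi_albert(4, 1, seed=8)
        params = ColumnParams()
        coup = CouplingParams(alpha=30.0, beta=12.0)
        drive = DriveParams()
        state = rng.normal(0, 3, 24)

        def rhs_flat(y):
            from nmmnet.network import coupling_drives

            Y = y.reshape(4, 6)
            pa, pb = coupling_drives(
                Y[:, 1] - Y[:, 2], Y[:, 0], topo, coup, params
            )
            out = np.empty_like(Y)
            for i in range(4):
                out[i] = column_rhs(Y[i], 0.25, drive, pa[i], pb[i], params)
            return out.ravel()

        J = system_jacobian(state, 0.25, topo, params, coup)
        h = 1e-6
        fd = np.empty_like(J)
        for k in range(24):
            e = np.zeros(24)
            e[k] = h
            fd[:, k] = (rhs_flat(state + e) - rhs_flat(state - e)) / (2 * h)
        scale = np.max(np.abs(J))
        assert np.max(np.abs(J - fd)) / scale < 1e-6

    def test_decoupled_is_block_diagonal(self, rng):
        topo = generate_barabasi_albert(3, 1, seed=1)
        J = system_jacobian(rng.normal(0, 2, 18), 0.0, topo,
                            ColumnParams(), CouplingParams(0.0, 0.0))
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert np.all(J[6 * i:6 * i + 6, 6 * j:6 * j + 6] == 0.0)

    def test_operator_rows(self, params):
        """Velocity rows carry -2k on the diagonal and -k^2 on the
        position column (k = a for y0/y1, k = b for y2)."""
        J = system_jacobian(np.zeros(6), 0.0, None, params)
        a, b = params.a, params.b
        assert J[3, 3] == -2 * a and J[3, 0] == -(a**2)
        assert J[4, 4] == -2 * a and J[4, 1] == -(a**2)
        assert J[5, 5] == -2 * b and J[5, 2] == -(b**2)


class TestGenericSpectrum:
    def test_linear_decay_exponent(self):
        """dy/dt = -a y has the single exponent -a."""
        a = 2.0
        res = lyapunov_spectrum_generic(
            lambda y, t: -a * y,
            lambda y, t: np.array([[-a]]),
            np.array([1.0]), 1e-3, 20.0,
        )
        assert res.exponents[0] == pytest.approx(-a, rel=1e-3)

    def test_lorenz_benchmark(self):
        """Canonical Lorenz MLE ~ 0.906; QR and Benettin agree."""
        y0 = np.array([1.0, 1.0, 1.0])
        res = lyapunov_spectrum_generic(
            lorenz_rhs, lorenz_jac, y0, 1e-3, 120.0, t_transient=20.0,
            reortho_every=5,
        )
        assert res.exponents[0] == pytest.approx(0.906, abs=0.05)
        # dissipative: exponent sum equals the (constant) trace
        trace = -10.0 - 1.0 - 8.0 / 3.0
        assert res.exponent_sum == pytest.approx(trace, rel=0.02)
        ben = benettin_mle_generic(lorenz_rhs, y0, 1e-3, 120.0, t_transient=20.0)
        assert ben == pytest.approx(res.exponents[0], rel=0.05)


class TestColumnSpectrum:
    def test_exponent_sum_equals_jacobian_trace(self, chaos_drive):
        """The column Jacobian trace is the constant -(4a + 2b) = -500/s;
        the exponent sum must match it."""
        res = lyapunov_spectrum(
            None, drive=chaos_drive, config=SHORT_LYAP,
        )
        assert res.exponent_sum == pytest.approx(-500.0, rel=0.02)
        assert np.all(np.diff(res.exponents) <= 1e-12)  # sorted descending

    def test_reorthonormalization_interval_invariance(self, chaos_drive):
        mles = [
            lyapunov_spectrum(
                None, drive=chaos_drive, config=SHORT_LYAP, reortho_every=k
            ).mle
            for k in (1, 5, 10)
        ]
        assert max(mles) - min(mles) < 0.05 * abs(np.mean(mles)) + 0.05

    def test_compiled_path_matches_generic_reference(self, undriven):
        """Cross-check of the compiled kernel against the pure Python QR
        implementation on the undriven limit cycle, where the spectrum is
        well-defined at short horizons (no chaotic trajectory drift)."""
        cfg = SimulationConfig(
            t_total=30.0, t_transient=10.0, method="adams_bashforth", seed=3
        )
        from nmmnet.simulate import draw_initial_conditions

        ic = draw_initial_conditions(1, cfg)
        res_fast = lyapunov_spectrum(
            None, drive=undriven, config=cfg, initial_states=ic
        )
        params = ColumnParams()

        def rhs(y, t):
            return column_rhs(y, t, undriven, 0.0, 0.0, params)

        def jac(y, t):
            return system_jacobian(y, t, None, params)

        res_ref = lyapunov_spectrum_generic(
            rhs, jac, ic.ravel(), cfg.dt, cfg.t_total, cfg.t_transient
        )
        assert res_fast.exponents == pytest.approx(res_ref.exponents, abs=0.3)
        assert res_fast.exponent_sum == pytest.approx(res_ref.exponent_sum, rel=0.02)

    def test_undriven_column_is_marginal(self, undriven):
        """A limit cycle has a zero leading exponent."""
        res = lyapunov_spectrum(None, drive=undriven, config=SHORT_LYAP)
        assert abs(res.mle) < 0.2

    def test_convergence_trace_approaches_final(self, chaos_drive):
        res = lyapunov_spectrum(None, drive=chaos_drive, config=SHORT_LYAP)
        assert res.convergence_trace[-1] == pytest.approx(res.mle, abs=0.05)


class TestMleMap:
    def test_single_cell_positive_at_chaos_point(self):
        grid = mle_map(
            [8.5], [0.49], config=SHORT_LYAP, n_seeds=2,
        )
        assert grid.values.shape == (1, 1)
        assert grid.values[0, 0] > 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            mle_map([], [0.49])
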