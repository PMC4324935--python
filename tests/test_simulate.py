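"""Integrators and network simulation contracts."""

import math

import numpy as np
import pytest

from nmmnet import (
    CouplingParams,
    DriveParams,
    NumericalBlowUp,
    SimulationConfig,
    adams_bashforth_step,
    draw_initial_conditions,
    heun_step,
    make_toy_network,
    regularity_single,
    simulate_column,
    simulate_network,
)


class TestHeunStep:
    def test_exponential_decay_closed_form(self):
        # one Heun step of dy/dt = -y from 1: 1 - dt + dt^2/2
        out = heun_step(lambda y, t: -y, np.array([1.0]), 0.0, 1e-3)
        assert out[0] == pytest.approx(1 - 1e-3 + 0.5e-6, rel=1e-15)

    def test_zero_field_leaves_state(self):
        out = heun_step(lambda y, t: 0.0 * y, np.array([2.0, -3.0]), 0.0, 0.1)
        assert out == pytest.approx([2.0, -3.0])

    def test_explicit_time_dependence(self):
        # dy/dt = t from 0 at t=0, dt=0.1: 0.05*(0 + 0.1) = 0.005
        out = heun_step(lambda y, t: np.array([t]), np.array([0.0]), 0.0, 0.1)
        assert out[0] == pytest.approx(0.005)

    def test_blowup_raises(self):
        with pytest.raises(NumericalBlowUp):
            heun_step(lambda y, t: np.array([np.inf]), np.array([1.0]), 0.0, 0.1)


class TestAdamsBashforthStep:
    def test_constant_field_exact(self):
        f = lambda y, t: np.array([3.0])
        out, fc = adams_bashforth_step(f, np.array([3.0]), np.array([1.0]), 0.0, 0.01)
        assert out[0] == pytest.approx(1.03)
        assert fc[0] == 3.0

    def test_exponential_decay_accuracy(self):
        # integrate dy/dt = -y over 1 s; AB2 bootstrapped by one Heun step
        dt = 1e-3
        rhs = lambda y, t: -y
        y = np.array([1.0])
        f_prev = rhs(y, 0.0)
        y = heun_step(rhs, y, 0.0, dt)
        for k in range(1, 1000):
            y, f_prev = adams_bashforth_step(rhs, f_prev, y, k * dt, dt)
        assert y[0] == pytest.approx(math.exp(-1.0), abs=1e-5)


class TestInitialConditions:
    def test_degenerate_bounds_give_exact_value(self):
        cfg = SimulationConfig(ic_low=0.0, ic_high=0.0)
        assert np.all(draw_initial_conditions(3, cfg) == 0.0)

    def test_seeded_reproducibility_and_range(self):
        cfg = SimulationConfig(seed=7)
        a = draw_initial_conditions(50, cfg)
        b = draw_initial_conditions(50, cfg)
        assert np.array_equal(a, b)
        assert a.shape == (50, 6)
        assert np.all((a >= cfg.ic_low) & (a <= cfg.ic_high))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(ic_low=1.0, ic_high=0.0)


class TestSimulateNetwork:
    def test_time_grid_and_output_identity(self, short_config):
        ts = simulate_column(config=short_config, store_states=True)
        assert np.allclose(np.diff(ts.times), short_config.dt)
        assert ts.times[0] == pytest.approx(short_config.t_transient)
        assert ts.outputs[0] == pytest.approx(ts.states[0, 1] - ts.states[0, 2])

    def test_bit_identical_repeats(self, short_config):
        a = simulate_column(config=short_config)
        b = simulate_column(config=short_config)
        assert np.array_equal(a.outputs, b.outputs)

    def test_decoupled_limit_equals_single_column(self, short_config):
        """alpha = beta = 0 with identical per-node ICs reproduces the
        isolated column trajectory exactly (not statistically)."""
        topo = make_toy_network("ring", 3)
        ic = draw_initial_conditions(1, short_config)
        ics = np.tile(ic, (3, 1))
        net = simulate_network(
            topo, coupling=CouplingParams(0.0, 0.0), config=short_config,
            initial_states=ics,
        )
        single = simulate_column(config=short_config, initial_state=ic[0])
        for i in range(3):
            assert np.array_equal(net.outputs[i], single.outputs[0])

    def test_methods_agree_on_short_horizon(self):
        """Heun and Adams-Bashforth are both second order: before phase
        error accumulates on the limit cycle their trajectories coincide."""
        from dataclasses import replace

        cfg = SimulationConfig(dt=1e-4, t_total=1.0, t_transient=0.0, seed=0)
        heun = simulate_column(drive=DriveParams(delta=0.0), config=cfg)
        ab = simulate_column(
            drive=DriveParams(delta=0.0),
            config=replace(cfg, method="adams_bashforth"),
        )
        assert np.max(np.abs(heun.outputs - ab.outputs)) < 5e-3

    def test_long_run_bounded(self, chaos_drive):
        cfg = SimulationConfig(t_total=20.0, t_transient=0.0, seed=2)
        ts = simulate_column(drive=chaos_drive, config=cfg)
        assert np.max(np.abs(ts.outputs)) < 100.0  # physiological bounds

    def test_blowup_reports_time(self):
        """Numerical instability (step far beyond the stability limit of
        the fast dendritic rates) must fail loudly, naming the time."""
        cfg = SimulationConfig(dt=0.05, t_total=5.0, t_transient=0.0)
        with pytest.raises(NumericalBlowUp, match="t="):
            simulate_column(drive=DriveParams(delta=0.0), config=cfg)

    def test_step_halving_leaves_statistics(self, chaos_drive):
        """Halving dt moves the mean activity and Reg by less than the
        across-seed spread at the standard operating point."""
        from dataclasses import replace

        base = SimulationConfig(t_total=15.0, t_transient=5.0)
        stats = {"dt": [], "seed": []}
        for seed in (0, 1, 2):
            ts = simulate_column(
                drive=chaos_drive, config=replace(base, seed=seed)
            )
            stats["seed"].append(
                (ts.outputs[0].mean(), regularity_single(ts.outputs[0]))
            )
        for dt in (1e-3, 5e-4):
            ts = simulate_column(
                drive=chaos_drive, config=replace(base, seed=0, dt=dt)
            )
            stats["dt"].append(
                (ts.outputs[0].mean(), regularity_single(ts.outputs[0]))
            )
        seed_spread = np.ptp(np.asarray(stats["seed"]), axis=0)
        dt_shift = np.abs(np.diff(np.asarray(stats["dt"]), axis=0))[0]
        assert np.all(dt_shift <= seed_spread + 1e-9)

    def test_trajectory_writer_roundtrip(self, tmp_path, short_config):
        ts = simulate_column(config=short_config)
        path = tmp_path / "run.tsv"
        ts.write(path)
        table = np.loadtxt(path, skiprows=1)
        assert table.shape == (ts.times.size, 2)
        assert table[:, 1] == pytest.approx(ts.outputs[0], abs=1e-5)
        assert (tmp_path / "run.tsv.meta.json").exists()
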