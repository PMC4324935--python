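"""Two diffusively coupled Wilson-Cowan oscillators.

Each oscillator holds an excitatory pool ``x`` and an inhibitory pool ``y``
with logistic activation ``S(v) = 1/(1+exp(-v))``:

    dx_i/dt = -x_i + S(a x_i - b y_i + p_i) + k_exc (x_j - x_i)
    dy_i/dt = -y_i + S(c x_i - d y_i + q_i) + k_inh (y_j - y_i)

The coupling is diffusive and symmetric: excitatory pools couple to
excitatory pools with strength ``k_exc`` and inhibitory to inhibitory with
``k_inh``.  The observable mirroring the cortical-column output is
``x_i - y_i``; the pair is *segregated* when the time averages
``<x_1 - y_1>`` and ``<x_2 - y_2>`` have opposite signs, which requires the
two oscillators to receive different external stimuli.

Note on the default gains: ``d = -2`` is used exactly as printed in the
source parameterization, which makes the ``- d y`` term inside the
inhibitory activation positive (self-excitation of the inhibitory pool).
``flip_d_sign=True`` switches to the conventional self-inhibition reading
for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core_model import NumericalBlowUp
from .sweep import SweepResult

__all__ = ["WCParams", "WCState", "wc_sigmoid", "wc_derivatives", "wc_simulate",
           "wc_segregation", "wc_segregation_map"]


@dataclass(frozen=True)
class WCParams:
    """Gains, stimuli and coupling strengths (all dimensionless)."""

    a: float = 16.0
    b: float = 12.0
    c: float = 16.0
    d: float = -2.0
    p1: float = -3.5
    p2: float = -1.0
    q1: float = -6.5
    q2: float = -4.0
    k_exc: float = 0.0
    k_inh: float = 0.0
    flip_d_sign: bool = False

    def __post_init__(self) -> None:
        if self.k_exc < 0 or self.k_inh < 0:
            raise ValueError("coupling strengths must be nonnegative")

    @property
    def d_eff(self) -> float:
        return -self.d if self.flip_d_sign else self.d


@dataclass(frozen=True)
class WCState:
    """Pool activities ``(x1, y1, x2, y2)``; bounded by the unit-interval
    attracting region after transients."""

    x1: float = 0.0
    y1: float = 0.0
    x2: float = 0.0
    y2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2])

    @classmethod
    def from_array(cls, s) -> "WCState":
        return cls(*np.asarray(s, dtype=float).reshape(4))


def wc_sigmoid(v):
    """Logistic activation ``1 / (1 + exp(-v))``."""
    return 1.0 / (1.0 + np.exp(-np.clip(v, -500.0, 500.0)))


def wc_derivatives(state: WCState | np.ndarray, params: WCParams) -> np.ndarray:
    """RHS of the coupled pair at ``state`` (array order x1, y1, x2, y2)."""
    if isinstance(state, WCState):
        state = state.as_array()
    x1, y1, x2, y2 = np.asarray(state, dtype=float)
    p = params
    d = p.d_eff
    return np.array(
        [
            -x1 + wc_sigmoid(p.a * x1 - p.b * y1 + p.p1) + p.k_exc * (x2 - x1),
            -y1 + wc_sigmoid(p.c * x1 - d * y1 + p.q1) + p.k_inh * (y2 - y1),
            -x2 + wc_sigmoid(p.a * x2 - p.b * y2 + p.p2) + p.k_exc * (x1 - x2),
            -y2 + wc_sigmoid(p.c * x2 - d * y2 + p.q2) + p.k_inh * (y1 - y2),
        ]
    )


def _draw_ic(seed: int) -> np.ndarray:
    return np.random.default_rng(seed).uniform(0.0, 1.0, size=4)


def wc_simulate(
    params: WCParams,
    t_total: float = 200.0,
    dt: float = 1e-3,
    t_transient: float = 100.0,
    seed: int = 0,
    initial_state: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Heun integration; returns ``(times, trajectory)`` with the
    transient discarded (trajectory shape ``(4, n_kept)``)."""
    if not 0 <= t_transient < t_total:
        raise ValueError("need 0 <= t_transient < t_total")
    s0 = _draw_ic(seed) if initial_state is None else np.asarray(initial_state, float)
    n_steps = int(round(t_total / dt))
    keep_from = int(round(t_transient / dt))
    p = params
    traj = _kernels.integrate_wilson_cowan(
        np.ascontiguousarray(s0), dt, n_steps, keep_from,
        p.a, p.b, p.c, p.d_eff, p.p1, p.p2, p.q1, p.q2, p.k_exc, p.k_inh,
    )
    if not np.all(np.isfinite(traj)):
        raise NumericalBlowUp("Wilson-Cowan trajectory left the finite range")
    times = dt * np.arange(keep_from, n_steps + 1)
    return times, traj


def wc_segregation(
    params: WCParams,
    t_total: float = 200.0,
    dt: float = 1e-3,
    t_transient: float = 100.0,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Time-averaged excitabilities ``(<x1-y1>, <x2-y2>)`` and whether the
    pair is segregated (averages of opposite signs)."""
    _, traj = wc_simulate(params, t_total, dt, t_transient, seed)
    m1 = float(np.mean(traj[0] - traj[1]))
    m2 = float(np.mean(traj[2] - traj[3]))
    return m1, m2, bool(m1 * m2 < 0.0)


def wc_segregation_map(
    k_exc_values,
    k_inh_values,
    params: WCParams = WCParams(),
    t_total: float = 200.0,
    dt: float = 1e-3,
    t_transient: float = 100.0,
    seed: int = 0,
) -> SweepResult:
    """Segregation over a (k_exc, k_inh) grid.

    Cell values are the signed product ``<x1-y1><x2-y2>`` clipped to its
    sign story: negative values mean segregation (opposite signs), with the
    magnitude grading how far apart the two excitabilities sit; the boolean
    criterion is simply ``value < 0``.
    """
    k_exc_values = np.asarray(list(k_exc_values), dtype=float)
    k_inh_values = np.asarray(list(k_inh_values), dtype=float)
    if k_exc_values.size == 0 or k_inh_values.size == 0:
        raise ValueError("coupling grids must be nonempty")
    grid = np.full((k_exc_values.size, k_inh_values.size), np.nan)
    invalid = []
    for i, ke in enumerate(k_exc_values):
        for j, ki in enumerate(k_inh_values):
            try:
                from dataclasses import replace

                m1, m2, _ = wc_segregation(
                    replace(params, k_exc=float(ke), k_inh=float(ki)),
                    t_total, dt, t_transient, seed,
                )
                grid[i, j] = m1 * m2
            except NumericalBlowUp:
                invalid.append((i, j))
    return SweepResult(
        axis1_name="k_exc",
        axis1_values=k_exc_values,
        axis2_name="k_inh",
        axis2_values=k_inh_values,
        metric_name="excitability_product",
        values=grid,
        n_realizations=1,
        seeds=[seed],
        invalid_cells=invalid,
    )
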