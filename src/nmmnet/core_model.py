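"""Single Jansen-Rit cortical column.

A cortical macrocolumn is described by three interacting mean-field
populations: pyramidal cells, excitatory interneurons and inhibitory
interneurons.  Two transformations generate the dynamics:

1. pulse density -> postsynaptic potential (PSP), a linear convolution with
   the alpha-function kernel ``h(t) = G k t exp(-k t)`` (``G`` in mV, ``k``
   in 1/s), equivalently the second-order operator
   ``y'' + 2 k y' + k^2 y = G k p(t)``;
2. net PSP -> firing rate, the sigmoid ``S(m) = 2 e0 / (1 + exp(r (nu0 - m)))``.

The column state is the triple of PSP variables ``(y0, y1, y2)`` — input to
the interneurons, excitatory input to the pyramidal population and
inhibitory input to the pyramidal population — plus their time derivatives
``(v0, v1, v2)`` from the first-order reduction of the operator.  The
analyzed observable is ``y1 - y2`` (EPSP minus IPSP on the pyramidal
population), the model's EEG-like output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColumnParams",
    "DriveParams",
    "ColumnState",
    "NumericalBlowUp",
    "sigmoid",
    "sigmoid_derivative",
    "psp_kernel",
    "column_rhs",
    "column_derivatives",
    "column_output",
]

#: clamp for the sigmoid exponent; exp(+-_EXP_CLIP) is finite in float64
_EXP_CLIP = 500.0


class NumericalBlowUp(RuntimeError):
    """Raised when a trajectory leaves the finite range during integration."""


@dataclass(frozen=True)
class ColumnParams:
    """Jansen-Rit column constants.

    Parameters
    ----------
    A, B : float
        Excitatory / inhibitory PSP amplitudes (mV).
    a, b : float
        Inverse excitatory / inhibitory dendritic time constants (1/s).
    C : float
        Base intra-column coupling constant (dimensionless).
    C1, C2, C3, C4 : float, optional
        Intra-column connectivity constants.  Default to the canonical
        multiples ``C, 0.8 C, 0.25 C, 0.25 C`` when not given.
    e0 : float
        Half of the maximum population firing rate (1/s).
    r : float
        Sigmoid steepness (1/mV).
    nu0 : float
        Net PSP producing the half-maximal firing rate (mV).
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    C: float = 133.5
    C1: float | None = None
    C2: float | None = None
    C3: float | None = None
    C4: float | None = None
    e0: float = 2.5
    r: float = 0.56
    nu0: float = 6.0

    def __post_init__(self) -> None:
        if self.C1 is None:
            object.__setattr__(self, "C1", self.C)
        if self.C2 is None:
            object.__setattr__(self, "C2", 0.8 * self.C)
        if self.C3 is None:
            object.__setattr__(self, "C3", 0.25 * self.C)
        if self.C4 is None:
            object.__setattr__(self, "C4", 0.25 * self.C)
        for name in ("A", "B", "a", "b", "C", "e0", "r", "nu0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ColumnParams.{name} must be strictly positive")


@dataclass(frozen=True)
class DriveParams:
    """External thalamic-like input to the pyramidal population.

    The pyramidal population of every column receives a constant pulse
    density ``p_bar`` plus a periodic component ``delta sin(2 pi f t +
    phase)`` mimicking rhythmic sensory/subcortical input.
    """

    p_bar: float = 155.0  # 1/s
    delta: float = 65.0  # 1/s
    f: float = 8.5  # Hz
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.p_bar < 0 or self.delta < 0 or self.f < 0:
            raise ValueError("p_bar, delta and f must be nonnegative")

    def value(self, t: float | np.ndarray) -> float | np.ndarray:
        """Total excitatory external pulse density at time ``t`` (1/s)."""
        return self.p_bar + self.delta * np.sin(2.0 * np.pi * self.f * t + self.phase)


@dataclass(frozen=True)
class ColumnState:
    """Six-dimensional column state: PSPs (mV) and their rates (mV/s)."""

    y0: float = 0.0
    y1: float = 0.0
    y2: float = 0.0
    v0: float = 0.0
    v1: float = 0.0
    v2: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.y0, self.y1, self.y2, self.v0, self.v1, self.v2])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ColumnState":
        y = np.asarray(y, dtype=float).reshape(6)
        return cls(*y)


def sigmoid(m, params: ColumnParams = ColumnParams()):
    """Firing rate (1/s) produced by a net PSP ``m`` (mV).

    ``S(m) = 2 e0 / (1 + exp(r (nu0 - m)))``, strictly inside ``(0, 2 e0)``
    and monotonically increasing.  The exponent is clamped so extreme
    transient PSPs cannot overflow.
    """
    z = np.clip(params.r * (params.nu0 - np.asarray(m, dtype=float)), -_EXP_CLIP, _EXP_CLIP)
    out = 2.0 * params.e0 / (1.0 + np.exp(z))
    return float(out) if np.isscalar(m) or np.ndim(m) == 0 else out


def sigmoid_derivative(m, params: ColumnParams = ColumnParams()):
    """dS/dm (1/s per mV); appears in the variational (Jacobian) equations."""
    z = np.clip(params.r * (params.nu0 - np.asarray(m, dtype=float)), -_EXP_CLIP, _EXP_CLIP)
    e = np.exp(z)
    out = 2.0 * params.e0 * params.r * e / (1.0 + e) ** 2
    return float(out) if np.isscalar(m) or np.ndim(m) == 0 else out


def psp_kernel(t, amplitude: float, rate: float):
    """Postsynaptic response kernel ``h(t) = amplitude * rate * t * exp(-rate t)``.

    Zero for ``t < 0`` (causality).  Peaks at ``t = 1/rate`` with height
    ``amplitude / e``.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0.0, amplitude * rate * t * np.exp(-rate * np.clip(t, 0.0, None)), 0.0)
    return float(out) if out.ndim == 0 else out


def column_rhs(
    y: np.ndarray,
    t: float,
    drive: DriveParams,
    p_alpha: float,
    p_beta: float,
    params: ColumnParams,
) -> np.ndarray:
    """Right-hand side of the six first-order column ODEs (array form).

    State ordering is ``(y0, y1, y2, v0, v1, v2)``.  Each PSP variable obeys
    ``y'' = G k (input pulse density) - 2 k y' - k^2 y`` with ``(G, k)``
    equal to ``(A, a)`` for the two excitatory variables and ``(B, b)`` for
    the inhibitory one.  ``p_alpha`` and ``p_beta`` are the excitatory and
    inhibitory pulse densities arriving from neighbor columns (1/s).
    """
    if p_alpha < 0 or p_beta < 0:
        raise ValueError("inter-column pulse densities must be nonnegative")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise NumericalBlowUp(f"non-finite column state at t={t:g} s")
    p = params
    y0, y1, y2, v0, v1, v2 = y
    s_pyr = sigmoid(y1 - y2, p)
    ext = drive.value(t)
    dv0 = p.A * p.a * s_pyr - 2.0 * p.a * v0 - p.a * p.a * y0
    dv1 = (
        p.A * p.a * (ext + p.C2 * sigmoid(p.C1 * y0, p) + p_alpha)
        - 2.0 * p.a * v1
        - p.a * p.a * y1
    )
    dv2 = p.B * p.b * (p.C4 * sigmoid(p.C3 * y0, p) + p_beta) - 2.0 * p.b * v2 - p.b * p.b * y2
    return np.array([v0, v1, v2, dv0, dv1, dv2])


def column_derivatives(
    state: ColumnState,
    t: float,
    drive: DriveParams,
    p_alpha: float,
    p_beta: float,
    params: ColumnParams,
) -> ColumnState:
    """Time derivative of a :class:`ColumnState` (typed wrapper of
    :func:`column_rhs`)."""
    return ColumnState.from_array(
        column_rhs(state.as_array(), t, drive, p_alpha, p_beta, params)
    )


def column_output(state) -> float:
    """EEG-like column observable ``y1 - y2`` (mV)."""
    if isinstance(state, ColumnState):
        return state.y1 - state.y2
    y = np.asarray(state, dtype=float)
    return float(y[1] - y[2])
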