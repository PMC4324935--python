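"""Deterministic synthetic signals and hand-enumerable toy topologies.

Every metric and integrator in the package is testable in milliseconds
against these generators; nothing here requires running a long simulation,
and everything is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkTopology

__all__ = ["SyntheticSignalSpec", "make_signal", "make_toy_network"]

_KINDS = ("sinusoid", "sum_of_sinusoids", "white_noise", "ar1", "shifted_copy", "constant")


@dataclass(frozen=True)
class SyntheticSignalSpec:
    """Recipe for a deterministic test signal.

    ``kind`` selects the generator; closed forms for the deterministic
    kinds are documented in :func:`make_signal`.  ``length`` is in seconds
    and ``rate`` in samples per second; the generated series has exactly
    ``round(length * rate)`` samples.
    """

    kind: str = "sinusoid"
    frequency: float = 10.0  # Hz (sinusoid); base frequency for sums
    frequencies: tuple = ()  # Hz, sum_of_sinusoids
    amplitude: float = 1.0
    noise_sd: float = 1.0
    ar_coeff: float = 0.9  # ar1
    shift: float = 0.1  # s, shifted_copy
    base: "SyntheticSignalSpec | None" = None  # shifted_copy source
    value: float = 0.0  # constant
    length: float = 25.0  # s
    rate: float = 1000.0  # 1/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}; choose from {_KINDS}")

    @property
    def n_samples(self) -> int:
        return int(round(self.length * self.rate))


def make_signal(spec: SyntheticSignalSpec) -> np.ndarray:
    """Generate the series described by ``spec``.

    Closed forms: ``sinusoid`` is ``amplitude sin(2 pi f t)``;
    ``sum_of_sinusoids`` sums unit sinusoids at ``frequencies``;
    ``constant`` is ``value`` everywhere; ``shifted_copy`` evaluates the
    base spec's closed form delayed by ``shift`` seconds (noise kinds are
    shifted by regenerating with the same seed, so the copy is exact).
    ``white_noise`` and ``ar1`` are seeded Gaussian processes.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.rate
    if spec.kind == "constant":
        return np.full(n, spec.value)
    if spec.kind == "sinusoid":
        return spec.amplitude * np.sin(2.0 * np.pi * spec.frequency * t)
    if spec.kind == "sum_of_sinusoids":
        freqs = spec.frequencies or (spec.frequency,)
        return sum(np.sin(2.0 * np.pi * f * t) for f in freqs) * spec.amplitude
    if spec.kind == "white_noise":
        rng = np.random.default_rng(spec.seed)
        return spec.noise_sd * rng.standard_normal(n)
    if spec.kind == "ar1":
        rng = np.random.default_rng(spec.seed)
        eps = spec.noise_sd * rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for k in range(1, n):
            x[k] = spec.ar_coeff * x[k - 1] + eps[k]
        return x
    if spec.kind == "shifted_copy":
        base = spec.base or SyntheticSignalSpec(
            kind="sinusoid", frequency=spec.frequency,
            length=spec.length + spec.shift, rate=spec.rate, seed=spec.seed,
        )
        from dataclasses import replace

        long = make_signal(replace(base, length=spec.length + spec.shift))
        k = int(round(spec.shift * spec.rate))
        return long[k : k + n] if k else long[:n]
    raise AssertionError("unreachable")


def make_toy_network(kind: str, n: int = 4) -> NetworkTopology:
    """Hand-enumerable topologies for exact coupling-sum tests.

    ``pair`` (two nodes, one edge), ``star`` (node 0 is the hub — exposes
    the ``1/(N_i N_j)`` normalization asymmetry), ``tree`` (binary tree on
    ``n`` nodes), ``ring`` (cycle).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if kind == "pair":
        return NetworkTopology.from_edges(2, [(0, 1)], {"algorithm": "toy_pair"})
    if kind == "star":
        return NetworkTopology.from_edges(
            n, [(0, i) for i in range(1, n)], {"algorithm": "toy_star", "n": n}
        )
    if kind == "tree":
        edges = [((i - 1) // 2, i) for i in range(1, n)]
        return NetworkTopology.from_edges(n, edges, {"algorithm": "toy_tree", "n": n})
    if kind == "ring":
        if n < 3:
            raise ValueError("ring needs n >= 3")
        edges = [(i, (i + 1) % n) for i in range(n)]
        return NetworkTopology.from_edges(n, edges, {"algorithm": "toy_ring", "n": n})
    raise ValueError(f"unknown toy network kind {kind!r}")
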