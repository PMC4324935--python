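"""Structured YAML configuration files.

A config file holds flat key/value sections, one per parameter group; every
key is optional and defaults reproduce the standard operating point:

.. code-block:: yaml

    column:      {A: 3.25, B: 22.0, a: 100.0, b: 50.0, C: 133.5}
    drive:       {p_bar: 155.0, delta: 65.0, f: 8.5, phase: 0.0}
    coupling:    {alpha_over_C: 0.56, beta_over_C: 0.26}
    simulation:  {dt: 0.001, t_total: 50.0, t_transient: 25.0, seed: 0}
    network:     {algorithm: barabasi_albert, n: 50, m0: 1, seed: 1}

Coupling may be given scaled (``alpha_over_C``/``beta_over_C``, matching
all figure axes) or raw (``alpha``/``beta`` in 1/s), not both.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .core_model import ColumnParams, DriveParams
from .network import (
    CouplingParams,
    NetworkTopology,
    generate_barabasi_albert,
    generate_watts_strogatz,
    read_edge_list,
)
from .simulate import SimulationConfig

__all__ = [
    "load_config",
    "column_params_from",
    "drive_params_from",
    "coupling_params_from",
    "simulation_config_from",
    "topology_from",
]


def load_config(path: str | Path) -> dict:
    """Parse a YAML config file into a plain dict of sections."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def column_params_from(cfg: dict) -> ColumnParams:
    return ColumnParams(**cfg.get("column", {}))


def drive_params_from(cfg: dict) -> DriveParams:
    return DriveParams(**cfg.get("drive", {}))


def coupling_params_from(cfg: dict, C: float | None = None) -> CouplingParams:
    sec = dict(cfg.get("coupling", {}))
    scaled = {"alpha_over_C", "beta_over_C"} & sec.keys()
    raw = {"alpha", "beta"} & sec.keys()
    if scaled and raw:
        raise ValueError("give coupling either scaled (alpha_over_C/beta_over_C) or raw (alpha/beta), not both")
    if scaled:
        if C is None:
            C = column_params_from(cfg).C
        return CouplingParams.from_scaled(
            sec.get("alpha_over_C", 0.0), sec.get("beta_over_C", 0.0), C
        )
    return CouplingParams(alpha=sec.get("alpha", 0.0), beta=sec.get("beta", 0.0))


def simulation_config_from(cfg: dict) -> SimulationConfig:
    return SimulationConfig(**cfg.get("simulation", {}))


def topology_from(cfg: dict) -> NetworkTopology:
    """Build the topology named in the ``network`` section.

    Algorithms: ``barabasi_albert`` (n, m0, seed), ``watts_strogatz``
    (n, k, rp, seed) and ``edge_list`` (path, optional n).
    """
    sec = dict(cfg.get("network", {}))
    algo = sec.pop("algorithm", "barabasi_albert")
    if algo == "barabasi_albert":
        return generate_barabasi_albert(
            sec.get("n", 50), sec.get("m0", 1), sec.get("seed")
        )
    if algo == "watts_strogatz":
        return generate_watts_strogatz(
            sec.get("n", 50), sec.get("k", 2), sec.get("rp", 0.0), sec.get("seed")
        )
    if algo == "edge_list":
        return read_edge_list(sec["path"], sec.get("n"))
    raise ValueError(f"unknown network algorithm {algo!r}")
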