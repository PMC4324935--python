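"""Grid-sweep result container shared by the lyapunov, wilson_cowan and
experiments modules."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SweepResult"]


@dataclass
class SweepResult:
    """Scalar metric on a 2-D parameter lattice with provenance.

    ``values[i, j]`` is the metric at ``(axis1_values[i], axis2_values[j])``;
    cells whose computation failed are NaN and listed in ``invalid_cells``.
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    metric_name: str
    values: np.ndarray
    n_realizations: int = 1
    seeds: list = field(default_factory=list)
    invalid_cells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis1_values = np.asarray(self.axis1_values, dtype=float)
        self.axis2_values = np.asarray(self.axis2_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.axis1_values.size, self.axis2_values.size)
        if self.values.shape != expected:
            raise ValueError(f"grid shape {self.values.shape} != {expected}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per grid cell."""
        rows = []
        for i, v1 in enumerate(self.axis1_values):
            for j, v2 in enumerate(self.axis2_values):
                rows.append((v1, v2, self.values[i, j]))
        return pd.DataFrame(rows, columns=[self.axis1_name, self.axis2_name, self.metric_name])

    def cell(self, v1: float, v2: float) -> float:
        i = int(np.argmin(np.abs(self.axis1_values - v1)))
        j = int(np.argmin(np.abs(self.axis2_values - v2)))
        return float(self.values[i, j])

    def save(self, path: str | Path) -> None:
        """Grid file with axis header rows plus a JSON manifest sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# metric: {self.metric_name}\n")
            fh.write(f"# rows: {self.axis1_name} = " + " ".join(map(str, self.axis1_values)) + "\n")
            fh.write(f"# cols: {self.axis2_name} = " + " ".join(map(str, self.axis2_values)) + "\n")
            np.savetxt(fh, self.values, delimiter="\t")
        manifest = {
            "metric": self.metric_name,
            "axis1": {"name": self.axis1_name, "values": self.axis1_values.tolist()},
            "axis2": {"name": self.axis2_name, "values": self.axis2_values.tolist()},
            "n_realizations": self.n_realizations,
            "seeds": [int(s) for s in self.seeds],
            "invalid_cells": [list(map(int, c)) for c in self.invalid_cells],
        }
        Path(f"{path}.meta.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SweepResult":
        path = Path(path)
        meta = json.loads(Path(f"{path}.meta.json").read_text())
        values = np.loadtxt(path, delimiter="\t", comments="#")
        values = np.atleast_2d(values)
        return cls(
            axis1_name=meta["axis1"]["name"],
            axis1_values=np.asarray(meta["axis1"]["values"]),
            axis2_name=meta["axis2"]["name"],
            axis2_values=np.asarray(meta["axis2"]["values"]),
            metric_name=meta["metric"],
            values=values,
            n_realizations=meta.get("n_realizations", 1),
            seeds=meta.get("seeds", []),
            invalid_cells=[tuple(c) for c in meta.get("invalid_cells", [])],
        )
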