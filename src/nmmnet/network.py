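"""Network topologies and inter-columnar coupling.

Columns are coupled bidirectionally on an undirected graph.  A node ``i``
receives from each neighbor ``j`` an excitatory pulse density driven by the
neighbor's pyramidal firing rate ``S(y1_j - y2_j)`` and an inhibitory pulse
density driven by ``S(C3 y0_j)``, each weighted by ``1 / (N_i N_j)`` where
``N_i`` is the undirected degree.  The weights guarantee that the summed
input to every node stays within the same bounded range regardless of
degree: ``p_alpha_i <= 2 e0 alpha`` and ``p_beta_i <= 2 e0 beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .core_model import ColumnParams, sigmoid

__all__ = [
    "NetworkTopology",
    "CouplingParams",
    "generate_barabasi_albert",
    "generate_watts_strogatz",
    "coupling_drives",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class CouplingParams:
    """Inter-columnar coupling strengths (1/s).

    ``alpha`` scales the excitatory (pyramidal -> pyramidal) pathway,
    ``beta`` the inhibitory (interneuron -> pyramidal) pathway.  Figures of
    merit are usually quoted in the scaled units ``alpha / C`` and
    ``beta / C``.
    """

    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("coupling strengths must be nonnegative")

    @classmethod
    def from_scaled(
        cls, alpha_over_C: float, beta_over_C: float, C: float = 133.5
    ) -> "CouplingParams":
        """Build from the scaled values used on all map axes."""
        return cls(alpha=alpha_over_C * C, beta=beta_over_C * C)

    def scaled(self, C: float = 133.5) -> tuple[float, float]:
        return self.alpha / C, self.beta / C


@dataclass(frozen=True)
class NetworkTopology:
    """Undirected, simple graph of cortical columns.

    ``edges`` are unordered 0-based index pairs stored with ``i < j``; the
    degree vector and sorted neighbor lists are derived and kept consistent
    by construction.  ``generator_meta`` records how the topology was made
    (algorithm, parameters, seed) for provenance.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    degree: np.ndarray
    neighbor_lists: tuple[np.ndarray, ...]
    generator_meta: dict = field(default_factory=dict)

    @classmethod
    def from_edges(
        cls, n_nodes: int, edges, generator_meta: dict | None = None
    ) -> "NetworkTopology":
        norm = set()
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < n_nodes and 0 <= j < n_nodes):
                raise ValueError(f"edge ({i},{j}) outside 0..{n_nodes - 1}")
            key = (min(i, j), max(i, j))
            if key in norm:
                raise ValueError(f"duplicate edge {key}")
            norm.add(key)
        edge_tuple = tuple(sorted(norm))
        nbrs: list[list[int]] = [[] for _ in range(n_nodes)]
        for i, j in edge_tuple:
            nbrs[i].append(j)
            nbrs[j].append(i)
        neighbor_lists = tuple(np.array(sorted(ns), dtype=np.int64) for ns in nbrs)
        degree = np.array([len(ns) for ns in neighbor_lists], dtype=np.int64)
        return cls(
            n_nodes=n_nodes,
            edges=edge_tuple,
            degree=degree,
            neighbor_lists=neighbor_lists,
            generator_meta=dict(generator_meta or {}),
        )

    @classmethod
    def from_graph(cls, g: nx.Graph, generator_meta: dict | None = None) -> "NetworkTopology":
        g = nx.convert_node_labels_to_integers(g, ordering="sorted")
        return cls.from_edges(g.number_of_nodes(), g.edges(), generator_meta)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def coupling_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR arrays ``(indptr, indices, weights)`` with weights
        ``1 / (N_i N_j)``; rows of degree-0 nodes are empty."""
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        indptr[1:] = np.cumsum(self.degree)
        indices = np.concatenate(
            [ns for ns in self.neighbor_lists] or [np.empty(0, dtype=np.int64)]
        ).astype(np.int64)
        deg = self.degree.astype(float)
        weights = np.empty(indices.size, dtype=float)
        for i in range(self.n_nodes):
            lo, hi = indptr[i], indptr[i + 1]
            if hi > lo:
                weights[lo:hi] = 1.0 / (deg[i] * deg[indices[lo:hi]])
        return indptr, indices, weights

    def coupling_matrix(self) -> sp.csr_matrix:
        indptr, indices, weights = self.coupling_csr()
        return sp.csr_matrix((weights, indices, indptr), shape=(self.n_nodes, self.n_nodes))

    def hash(self) -> str:
        """Stable short hash of the edge set, for provenance sidecars."""
        import hashlib

        payload = f"{self.n_nodes}:" + ";".join(f"{i},{j}" for i, j in self.edges)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def generate_barabasi_albert(n: int, m0: int = 1, seed: int | None = None) -> NetworkTopology:
    """Scale-free topology by preferential attachment.

    Growth starts from ``m0`` nodes; every new node attaches ``m0`` links to
    existing nodes with probability proportional to their degree.  With
    ``m0 = 1`` the result is a tree dominated by a few connector hubs.
    """
    if m0 < 1:
        raise ValueError("m0 must be >= 1")
    if n <= m0:
        raise ValueError("need n > m0")
    g = nx.barabasi_albert_graph(n, m0, seed=seed)
    return NetworkTopology.from_graph(
        g, {"algorithm": "barabasi_albert", "n": n, "m0": m0, "seed": seed}
    )


def generate_watts_strogatz(
    n: int, k: int, rp: float, seed: int | None = None
) -> NetworkTopology:
    """Ring / small-world / random topology by Watts-Strogatz rewiring.

    ``rp = 0`` leaves the regular ring with ``k`` neighbors per node,
    ``rp = 0.5`` yields a small-world graph and ``rp = 1`` a fully rewired
    (random) one.
    """
    if k % 2 != 0:
        raise ValueError("k must be even (k/2 neighbors on each side of the ring)")
    if not 0.0 <= rp <= 1.0:
        raise ValueError("rewiring probability must lie in [0, 1]")
    if n <= k:
        raise ValueError("need n > k")
    g = nx.watts_strogatz_graph(n, k, rp, seed=seed)
    return NetworkTopology.from_graph(
        g, {"algorithm": "watts_strogatz", "n": n, "k": k, "rp": rp, "seed": seed}
    )


def coupling_drives(
    outputs_exc: np.ndarray,
    outputs_y0: np.ndarray,
    topology: NetworkTopology,
    coupling: CouplingParams,
    params: ColumnParams = ColumnParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node inter-columnar pulse densities ``(p_alpha, p_beta)`` (1/s).

    ``p_alpha_i = alpha sum_j w_ij S(y1_j - y2_j)`` and
    ``p_beta_i = beta sum_j w_ij S(C3 y0_j)`` with ``w_ij = 1/(N_i N_j)``
    over the neighbors of ``i``.  Degree-0 nodes receive exactly zero.
    """
    outputs_exc = np.asarray(outputs_exc, dtype=float)
    outputs_y0 = np.asarray(outputs_y0, dtype=float)
    if outputs_exc.shape != (topology.n_nodes,) or outputs_y0.shape != (topology.n_nodes,):
        raise ValueError("per-node arrays must have length n_nodes")
    w = topology.coupling_matrix()
    p_alpha = coupling.alpha * (w @ sigmoid(outputs_exc, params))
    p_beta = coupling.beta * (w @ sigmoid(params.C3 * outputs_y0, params))
    return p_alpha, p_beta


def write_edge_list(topology: NetworkTopology, path: str | Path) -> None:
    """Write ``i j`` per line (0-based, undirected, no header)."""
    with open(path, "w") as fh:
        for i, j in topology.edges:
            fh.write(f"{i} {j}\n")


def read_edge_list(path: str | Path, n_nodes: int | None = None) -> NetworkTopology:
    """Read a whitespace-separated two-column edge list (0-based indices)."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            edges.append((int(parts[0]), int(parts[1])))
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=-1)
    return NetworkTopology.from_edges(
        n_nodes, edges, {"algorithm": "edge_list", "path": str(path)}
    )
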