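"""Reproducible experiment pipelines.

Each function reruns one of the study designs end to end — parameter
sweeps of the driven single column, coupling sweeps and pairwise
synchronization analysis of one 50-node network, and multi-network
segregation ensembles — as a pure function of its parameters and a master
seed, so rerunning reproduces identical numbers.

Seeding scheme: every (cell, realization) task derives its integer seed
from ``numpy.random.SeedSequence(master_seed).spawn`` by flat task counter
``cell_index * n_realizations + realization``, keeping tasks independent
and individually regenerable.

Ensemble sizes default to the full study design (50 networks for the
segregation/degree reports, 10 networks per cell for the EIS map, 20
initial-condition realizations for the coupling sweep); the ``scale_down``
factor divides them uniformly for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import ColumnParams, DriveParams, NumericalBlowUp
from .lyapunov import mle_map
from .metrics import (
    ActivityDistribution,
    classify_node,
    eis_index,
    max_cross_correlation,
    regularity_single,
)
from .network import CouplingParams, NetworkTopology, generate_barabasi_albert
from .simulate import SimulationConfig, simulate_column, simulate_network
from .sweep import SweepResult

__all__ = [
    "EnsembleReport",
    "SweepResult",
    "task_seeds",
    "run_drive_sweep",
    "run_coupling_sweep",
    "run_pair_analysis",
    "run_segregation_ensemble",
    "run_eis_map",
    "run_degree_report",
]


def task_seeds(master_seed: int, n_tasks: int) -> list[int]:
    """Deterministic per-task integer seeds (< 2**31) from a master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n_tasks)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _scaled(n: int, scale_down: float) -> int:
    return max(1, int(round(n / scale_down)))


@dataclass
class EnsembleReport:
    """Multi-network segregation summary.

    ``nodes`` has one row per (network, node) with degree, mean activity,
    E/I class and regularity; ``distribution`` pools the mean activities;
    ``eis`` and ``fraction_inhibitory`` are computed from the pool.
    """

    nodes: pd.DataFrame
    distribution: ActivityDistribution
    eis: float
    fraction_inhibitory: float
    n_networks: int
    n_failed: int = 0
    meta: dict = field(default_factory=dict)


def run_drive_sweep(
    f_values,
    delta_over_C_values,
    params: ColumnParams = ColumnParams(),
    p_bar: float = 155.0,
    n_seeds: int = 5,
    master_seed: int = 0,
    metrics_config: SimulationConfig = SimulationConfig(),
    lyapunov_config: SimulationConfig | None = None,
) -> tuple[SweepResult, SweepResult]:
    """Chaos map of the driven single column: (MLE grid, Reg grid).

    For every (drive frequency, scaled amplitude) cell the column is
    simulated across seeds; the MLE comes from the variational QR method
    and Reg from the autocorrelation of the retained output.
    """
    from .lyapunov import LYAPUNOV_CONFIG

    if lyapunov_config is None:
        lyapunov_config = LYAPUNOV_CONFIG
    f_values = np.asarray(list(f_values), dtype=float)
    dC_values = np.asarray(list(delta_over_C_values), dtype=float)
    mle_grid = mle_map(
        f_values, dC_values, params,
        replace(lyapunov_config, seed=master_seed), n_seeds, p_bar,
    )
    reg_grid = np.full((f_values.size, dC_values.size), np.nan)
    invalid = []
    seeds = task_seeds(master_seed, f_values.size * dC_values.size * n_seeds)
    for i, f in enumerate(f_values):
        for j, dC in enumerate(dC_values):
            cell = i * dC_values.size + j
            drive = DriveParams(p_bar=p_bar, delta=dC * params.C, f=float(f))
            vals = []
            for r in range(n_seeds):
                s = seeds[cell * n_seeds + r]
                try:
                    ts = simulate_column(params, drive, replace(metrics_config, seed=s))
                    vals.append(regularity_single(ts.outputs[0]))
                except NumericalBlowUp:
                    pass
            if vals:
                reg_grid[i, j] = float(np.mean(vals))
            else:
                invalid.append((i, j))
    reg = SweepResult(
        axis1_name="f_Hz", axis1_values=f_values,
        axis2_name="delta_over_C", axis2_values=dC_values,
        metric_name="regularity", values=reg_grid,
        n_realizations=n_seeds, seeds=seeds, invalid_cells=invalid,
    )
    return mle_grid, reg


def run_coupling_sweep(
    alpha_over_C_values,
    beta_over_C_values,
    topology: NetworkTopology,
    params: ColumnParams = ColumnParams(),
    drive: DriveParams = DriveParams(),
    n_seeds: int = 20,
    master_seed: int = 0,
    config: SimulationConfig = SimulationConfig(),
    scale_down: float = 1.0,
) -> SweepResult:
    """Network-averaged regularity over the (alpha/C, beta/C) lattice for
    one fixed topology."""
    a_values = np.asarray(list(alpha_over_C_values), dtype=float)
    b_values = np.asarray(list(beta_over_C_values), dtype=float)
    if a_values.size == 0 or b_values.size == 0:
        raise ValueError("sweep grids must be nonempty")
    n_seeds = _scaled(n_seeds, scale_down)
    grid = np.full((a_values.size, b_values.size), np.nan)
    invalid = []
    seeds = task_seeds(master_seed, a_values.size * b_values.size * n_seeds)
    for i, aC in enumerate(a_values):
        for j, bC in enumerate(b_values):
            cell = i * b_values.size + j
            coupling = CouplingParams.from_scaled(aC, bC, params.C)
            vals = []
            for r in range(n_seeds):
                s = seeds[cell * n_seeds + r]
                try:
                    ts = simulate_network(
                        topology, params, drive, coupling, replace(config, seed=s)
                    )
                    vals.extend(regularity_single(ts.outputs[k]) for k in range(ts.n_nodes))
                except NumericalBlowUp:
                    pass
            if vals:
                grid[i, j] = float(np.mean(vals))
            else:
                invalid.append((i, j))
    return SweepResult(
        axis1_name="alpha_over_C", axis1_values=a_values,
        axis2_name="beta_over_C", axis2_values=b_values,
        metric_name="regularity", values=grid,
        n_realizations=n_seeds, seeds=seeds, invalid_cells=invalid,
    )


def run_pair_analysis(
    topology: NetworkTopology,
    alpha_over_C: float,
    beta_over_C: float,
    params: ColumnParams = ColumnParams(),
    drive: DriveParams = DriveParams(),
    config: SimulationConfig = SimulationConfig(),
    max_lag_s: float = 1.0,
) -> pd.DataFrame:
    """All-pairs synchronization table for one simulated network.

    One row per unordered node pair with the maximal cross-correlation
    ``C_max``, its lag, whether the pair is directly connected, and the
    pair-averaged regularity; sorted by increasing ``C_max``.  Zero-variance
    nodes are excluded with a warning column absent — they simply do not
    appear in any pair.
    """
    import warnings

    coupling = CouplingParams.from_scaled(alpha_over_C, beta_over_C, params.C)
    ts = simulate_network(topology, params, drive, coupling, config)
    max_lag = int(round(max_lag_s * ts.sampling_rate))
    edge_set = set(topology.edges)
    reg = {}
    valid = []
    for i in range(ts.n_nodes):
        if ts.outputs[i].std() < 1e-15:
            warnings.warn(f"node {i} has zero-variance output; excluded from pairs")
            continue
        valid.append(i)
        reg[i] = regularity_single(ts.outputs[i])
    rows = []
    for ii, i in enumerate(valid):
        for j in valid[ii + 1 :]:
            cmax, lag = max_cross_correlation(ts.outputs[i], ts.outputs[j], max_lag)
            rows.append(
                (i, j, (i, j) in edge_set, cmax, lag / ts.sampling_rate,
                 0.5 * (reg[i] + reg[j]))
            )
    df = pd.DataFrame(
        rows, columns=["i", "j", "connected", "c_max", "lag_s", "pair_regularity"]
    )
    return df.sort_values("c_max", kind="stable", ignore_index=True)


def run_segregation_ensemble(
    alpha_over_C: float,
    beta_over_C: float,
    n_networks: int = 50,
    n_nodes: int = 50,
    m0: int = 1,
    params: ColumnParams = ColumnParams(),
    drive: DriveParams = DriveParams(),
    config: SimulationConfig = SimulationConfig(),
    master_seed: int = 0,
    scale_down: float = 1.0,
    topology_factory=None,
    compute_regularity: bool = True,
) -> EnsembleReport:
    """Segregation statistics over an ensemble of random topologies.

    Each network is generated with its own seed, simulated once, and every
    node classified by the sign of its mean activity; the pooled activity
    distribution yields the EIS index and inhibitory fraction.  Failed
    networks are skipped and counted.  ``compute_regularity=False`` skips
    the per-node autocorrelation (the regularity column is NaN) when only
    the activity distribution is needed.
    """
    n_networks = _scaled(n_networks, scale_down)
    seeds = task_seeds(master_seed, 2 * n_networks)
    rows = []
    n_failed = 0
    for k in range(n_networks):
        topo_seed, ic_seed = seeds[2 * k], seeds[2 * k + 1]
        if topology_factory is None:
            topo = generate_barabasi_albert(n_nodes, m0, seed=topo_seed)
        else:
            topo = topology_factory(topo_seed)
        try:
            ts = simulate_network(
                topo, params, drive,
                CouplingParams.from_scaled(alpha_over_C, beta_over_C, params.C),
                replace(config, seed=ic_seed),
            )
        except NumericalBlowUp:
            n_failed += 1
            continue
        means = ts.mean_activity()
        for i in range(ts.n_nodes):
            reg_i = (
                regularity_single(ts.outputs[i]) if compute_regularity else float("nan")
            )
            rows.append(
                (k, i, int(topo.degree[i]), float(means[i]),
                 classify_node(means[i]), reg_i)
            )
    if not rows:
        raise RuntimeError("every network in the ensemble failed to integrate")
    nodes = pd.DataFrame(
        rows,
        columns=["network", "node_id", "degree", "mean_activity", "ei_class", "regularity"],
    )
    dist = ActivityDistribution(nodes["mean_activity"].to_numpy())
    return EnsembleReport(
        nodes=nodes,
        distribution=dist,
        eis=eis_index(dist),
        fraction_inhibitory=dist.fraction_inhibitory,
        n_networks=n_networks,
        n_failed=n_failed,
        meta={
            "alpha_over_C": alpha_over_C,
            "beta_over_C": beta_over_C,
            "n_nodes": n_nodes,
            "m0": m0,
            "master_seed": master_seed,
        },
    )


def run_eis_map(
    alpha_over_C_values,
    beta_over_C_values,
    n_networks: int = 10,
    n_nodes: int = 50,
    m0: int = 1,
    params: ColumnParams = ColumnParams(),
    drive: DriveParams = DriveParams(),
    config: SimulationConfig = SimulationConfig(),
    master_seed: int = 0,
    scale_down: float = 1.0,
) -> SweepResult:
    """EIS index over the coupling lattice, averaged over fresh random
    networks per cell; exhibits the no/low/strong segregation domains."""
    a_values = np.asarray(list(alpha_over_C_values), dtype=float)
    b_values = np.asarray(list(beta_over_C_values), dtype=float)
    if a_values.size == 0 or b_values.size == 0:
        raise ValueError("sweep grids must be nonempty")
    grid = np.full((a_values.size, b_values.size), np.nan)
    invalid = []
    for i, aC in enumerate(a_values):
        for j, bC in enumerate(b_values):
            cell = i * b_values.size + j
            try:
                rep = run_segregation_ensemble(
                    float(aC), float(bC), n_networks, n_nodes, m0,
                    params, drive, config,
                    master_seed=int(np.random.SeedSequence(
                        master_seed, spawn_key=(cell,)
                    ).generate_state(1)[0] % (2**31)),
                    scale_down=scale_down,
                    compute_regularity=False,
                )
                grid[i, j] = rep.eis
            except (RuntimeError, NumericalBlowUp):
                invalid.append((i, j))
    return SweepResult(
        axis1_name="alpha_over_C", axis1_values=a_values,
        axis2_name="beta_over_C", axis2_values=b_values,
        metric_name="eis", values=grid,
        n_realizations=n_networks, seeds=[master_seed], invalid_cells=invalid,
    )


def run_degree_report(
    alpha_over_C: float,
    beta_over_C: float,
    n_networks: int = 50,
    n_nodes: int = 50,
    m0: int = 1,
    params: ColumnParams = ColumnParams(),
    drive: DriveParams = DriveParams(),
    config: SimulationConfig = SimulationConfig(),
    master_seed: int = 0,
    scale_down: float = 1.0,
    topology_factory=None,
) -> dict:
    """Degree-vs-activity report across an ensemble.

    Returns the per-node table, per-degree aggregates (mean/SD of activity
    and regularity) and the Spearman rank correlation between degree and
    mean activity; when the degree is constant across nodes (regular
    topologies) the correlation is undefined and flagged.
    """
    from scipy import stats

    rep = run_segregation_ensemble(
        alpha_over_C, beta_over_C, n_networks, n_nodes, m0, params, drive,
        config, master_seed, scale_down, topology_factory,
    )
    nodes = rep.nodes
    by_degree = (
        nodes.groupby("degree")
        .agg(
            mean_activity=("mean_activity", "mean"),
            sd_activity=("mean_activity", "std"),
            mean_regularity=("regularity", "mean"),
            sd_regularity=("regularity", "std"),
            n=("node_id", "count"),
        )
        .reset_index()
    )
    degenerate = nodes["degree"].nunique() < 2
    if degenerate:
        rho, pval = float("nan"), float("nan")
    else:
        rho, pval = stats.spearmanr(nodes["degree"], nodes["mean_activity"])
    return {
        "nodes": nodes,
        "by_degree": by_degree,
        "degree_activity_spearman": float(rho),
        "degree_activity_pvalue": float(pval),
        "degree_degenerate": bool(degenerate),
        "ensemble": rep,
    }
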