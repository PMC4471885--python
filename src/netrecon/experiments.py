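"""Experiment grids: (mu, f) sweeps with realization averaging.

A sweep runs, for every (metric, mu, f) cell, a number of independent
realizations of the full chain — network draw (or fixed topology),
spreading simulation, all-pairs scoring, top-E reconstruction,
evaluation — and aggregates means and standard deviations. Per-cell
seeds are derived from the master seed and the cell indices, so each
cell is independently reproducible.

The special-range detector flags cells where a metric keeps a high AUC
while its top-E precision collapses toward the random baseline P0 — the
regime in which degree-punishing metrics (LHN most severely) place the
inferred links on nodes that should have low degree, and score
degeneracy forces large random tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netrecon.evaluate import evaluate_scores
from netrecon.generators import GeneratorSpec
from netrecon.graph import Network, read_edge_list
from netrecon.similarity import score_all_pairs
from netrecon.simulate import SimulationParams, run_spreading

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = [
    "metric", "mu", "f", "auc_mean", "auc_sd", "precision_mean",
    "precision_sd", "degcorr_mean", "degcorr_sd", "p0",
]


@dataclass(frozen=True)
class SweepConfig:
    """One experiment grid.

    ``network_spec`` is either a :class:`GeneratorSpec` (a fresh network
    is drawn per realization unless ``fix_topology``) or a
    :class:`Network` / edge-list path used as-is for every cell.
    """

    network_spec: object  # GeneratorSpec | Network | path
    mu_grid: tuple = (0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    f_grid: tuple = (0.5,)
    metrics: tuple = ("cn", "tcn", "jac", "tjac", "ra", "tra", "lhn", "tlhn")
    realizations: int = 50
    n_auc: int = 100_000
    master_seed: int = 0
    fix_topology: bool = False
    directed: bool = False

    def __post_init__(self):
        if not self.mu_grid or not self.f_grid or not self.metrics:
            raise ValueError("grids and metric list must be non-empty")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")


def _cell_seeds(master_seed: int, metric_idx: int, mu_idx: int, f_idx: int,
                realization: int) -> tuple[int, int, int, int]:
    """(network, spreading, reconstruction, auc) seeds for one cell run."""
    ss = np.random.SeedSequence(master_seed,
                                spawn_key=(metric_idx, mu_idx, f_idx, realization))
    return tuple(int(s) for s in ss.generate_state(4) & 0x7FFFFFFF)


def _resolve_network(spec, seed: int, directed: bool) -> Network:
    if isinstance(spec, Network):
        return spec
    if isinstance(spec, GeneratorSpec):
        return spec.realise(seed=seed)
    return read_edge_list(spec, directed=directed)


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run the grid; one row of realization-averaged metrics per cell.

    Row order is deterministic (metrics, then mu, then f, in config
    order). A failing cell is logged and skipped, not fatal to the
    sweep. Degree-correlation means ignore undefined (nan) realizations.
    """
    rows = []
    fixed_net = None
    if config.fix_topology or not isinstance(config.network_spec, GeneratorSpec):
        fixed_net = _resolve_network(config.network_spec,
                                     seed=int(np.random.SeedSequence(
                                         config.master_seed).generate_state(1)[0] & 0x7FFFFFFF),
                                     directed=config.directed)
    for mi, metric in enumerate(config.metrics):
        for ui, mu in enumerate(config.mu_grid):
            for fi, f in enumerate(config.f_grid):
                aucs, precs, dcorrs, p0 = [], [], [], None
                try:
                    for r in range(config.realizations):
                        net_seed, sim_seed, rec_seed, auc_seed = _cell_seeds(
                            config.master_seed, mi, ui, fi, r)
                        net = fixed_net if fixed_net is not None else _resolve_network(
                            config.network_spec, net_seed, config.directed)
                        record = run_spreading(net, SimulationParams(
                            submission_prob=f, infection_rate=mu, seed=sim_seed))
                        table = score_all_pairs(record, metric, directed=net.directed)
                        report = evaluate_scores(table, net, n_auc=config.n_auc,
                                                 seed=rec_seed)
                        aucs.append(report.auc)
                        precs.append(report.precision)
                        dcorrs.append(report.degree_correlation)
                        p0 = report.p0
                except Exception:
                    logger.exception("cell (metric=%s, mu=%g, f=%g) failed; skipping",
                                     metric, mu, f)
                    continue
                dcorrs = np.asarray(dcorrs, dtype=float)
                rows.append({
                    "metric": metric, "mu": mu, "f": f,
                    "auc_mean": float(np.mean(aucs)), "auc_sd": float(np.std(aucs)),
                    "precision_mean": float(np.mean(precs)),
                    "precision_sd": float(np.std(precs)),
                    "degcorr_mean": float(np.nanmean(dcorrs)) if not np.all(np.isnan(dcorrs)) else float("nan"),
                    "degcorr_sd": float(np.nanstd(dcorrs)) if not np.all(np.isnan(dcorrs)) else float("nan"),
                    "p0": p0,
                })
                logger.info("cell done: metric=%s mu=%g f=%g auc=%.3f prec=%.3f",
                            metric, mu, f, rows[-1]["auc_mean"], rows[-1]["precision_mean"])
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def special_range_report(sweep_output: pd.DataFrame, auc_min: float = 0.7,
                         precision_factor: float = 2.0) -> dict:
    """Per-metric list of mu values where precision collapses to ~P0.

    A cell is flagged when its mean AUC stays at or above ``auc_min``
    while its mean precision falls to at most ``precision_factor * P0``.
    Requires at least 3 distinct mu values per metric, so that "a range
    of mu" is meaningful.
    """
    out = {}
    for metric, grp in sweep_output.groupby("metric", sort=False):
        if grp["mu"].nunique() < 3:
            raise ValueError(f"metric {metric!r}: need >= 3 mu values, "
                             f"got {grp['mu'].nunique()}")
        flagged = grp[(grp["auc_mean"] >= auc_min)
                      & (grp["precision_mean"] <= precision_factor * grp["p0"])]
        out[metric] = sorted(flagged["mu"].unique().tolist())
    return out
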