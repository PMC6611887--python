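"""Planted-partition benchmarks and partition-recovery metrics.

The generator draws graphs from the symmetric stochastic block model: ``l``
communities of ``k`` vertices each, an edge between two vertices of the same
community with probability ``p_in`` and between communities with ``p_out``.
Two recovery metrics are provided:

* exact-match accuracy — the percentage of ground-truth communities whose
  member set is reproduced *exactly* by some predicted community;
* per-node misclassification — predicted communities are matched one-to-one
  to truth communities by a maximum-overlap assignment (solved exactly as an
  assignment problem), and every vertex outside its matched community counts
  as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import DetectionConfig, Partition, detect_communities

__all__ = [
    "SBMConfig",
    "AccuracyReport",
    "generate_sbm",
    "exact_match_accuracy",
    "node_misclassification",
    "run_accuracy_experiment",
]


@dataclass(frozen=True)
class SBMConfig:
    """Planted-partition parameters: l communities of k vertices."""

    k: int
    l: int
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.l < 1:
            raise ValueError("k and l must be >= 1")
        for p in (self.p_in, self.p_out):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class AccuracyReport:
    """Recovery metrics at one SBM grid point, aggregated over replicates."""

    config: SBMConfig
    replicates: pd.DataFrame

    @property
    def exact_match_mean(self) -> float:
        return float(self.replicates["exact_match_pct"].mean())

    @property
    def exact_match_sd(self) -> float:
        return float(self.replicates["exact_match_pct"].std(ddof=1)) if len(
            self.replicates
        ) > 1 else 0.0

    @property
    def misclassified_mean_pct(self) -> float:
        return float(self.replicates["misclassified_pct"].mean())

    @property
    def misclassified_sd_pct(self) -> float:
        return float(self.replicates["misclassified_pct"].std(ddof=1)) if len(
            self.replicates
        ) > 1 else 0.0


def generate_sbm(config: SBMConfig):
    """Draw one planted-partition graph; returns (graph, truth partition).

    Vertices are the integers 0 .. k*l - 1; community c is the consecutive
    block [c*k, (c+1)*k).  Reproducible from ``config.seed``.
    """
    g = nx.planted_partition_graph(
        config.l, config.k, config.p_in, config.p_out, seed=config.seed
    )
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(g.edges(), weight=1.0)
    truth = Partition(
        [range(c * config.k, (c + 1) * config.k) for c in range(config.l)]
    )
    return out, truth


def _check_same_vertices(pred: Partition, truth: Partition) -> None:
    if pred.vertices != truth.vertices:
        raise ValueError("partitions are over different vertex sets")


def exact_match_accuracy(pred: Partition, truth: Partition) -> float:
    """Percent of truth communities reproduced exactly as vertex sets."""
    _check_same_vertices(pred, truth)
    pred_sets = set(pred.to_sets())
    hits = sum(1 for t in truth.to_sets() if t in pred_sets)
    return 100.0 * hits / truth.n_communities


def node_misclassification(pred: Partition, truth: Partition):
    """(count, percent) of vertices misassigned under the best matching.

    Predicted communities are paired one-to-one with truth communities so as
    to maximize the total overlap; vertices not covered by a matched pair's
    intersection (including all members of unmatched predicted communities)
    are misclassified.
    """
    _check_same_vertices(pred, truth)
    P, T = pred.to_sets(), truth.to_sets()
    overlap = np.array([[len(p & t) for t in T] for p in P])
    rows, cols = linear_sum_assignment(overlap, maximize=True)
    matched = int(overlap[rows, cols].sum())
    count = len(pred) - matched
    return count, 100.0 * count / len(pred)


def run_accuracy_experiment(
    grid,
    replicates: int,
    base_seed: int = 0,
    detection: DetectionConfig | None = None,
):
    """Detection accuracy over an SBM grid.

    For each :class:`SBMConfig` in ``grid``, draws ``replicates`` graphs with
    seeds ``base_seed + r``, runs the detector, and scores both metrics
    against the planted communities.

    Returns (tidy ``pandas.DataFrame``, list of :class:`AccuracyReport`), the
    frame holding one row per (grid point, replicate).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    detection = detection or DetectionConfig()
    rows = []
    reports = []
    for cfg in grid:
        for r in range(replicates):
            seed = base_seed + r
            g, truth = generate_sbm(replace(cfg, seed=seed))
            res = detect_communities(g, config=detection)
            acc = exact_match_accuracy(res.partition, truth)
            mis_n, mis_pct = node_misclassification(res.partition, truth)
            rows.append(
                {
                    "k": cfg.k,
                    "l": cfg.l,
                    "p_in": cfg.p_in,
                    "p_out": cfg.p_out,
                    "replicate": r,
                    "seed": seed,
                    "n_communities_found": res.partition.n_communities,
                    "exact_match_pct": acc,
                    "misclassified_n": mis_n,
                    "misclassified_pct": mis_pct,
                }
            )
    frame = pd.DataFrame(rows)
    for cfg in grid:
        sub = frame[
            (frame["k"] == cfg.k)
            & (frame["l"] == cfg.l)
            & (frame["p_in"] == cfg.p_in)
            & (frame["p_out"] == cfg.p_out)
        ].reset_index(drop=True)
        reports.append(AccuracyReport(cfg, sub))
    return frame, reports
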