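"""Edge Ollivier-Ricci curvature on weighted graphs.

For an edge (i, j) the curvature is

    kappa(i, j) = 1 - W1(mu_i, mu_j) / d(i, j)

where mu_i puts mass rho_ik / sum_k rho_ik on each neighbor k of i, d is the
shortest-path metric induced by the edge weights, and W1 is the Wasserstein-1
(earth mover's) distance between the two neighborhood measures, computed as
an exact transportation linear program.  Edges inside densely interconnected
neighborhoods come out positive, bridges between such neighborhoods negative,
and edges hanging off degree-1 vertices exactly zero on unweighted graphs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import numpy as np

from ._engine import ZERO_TOL_DEFAULT, CurvatureEngine
from ._transport import solve_transport
from .graph import DistanceOracle, distances_between, edge_key, label_sort_key

__all__ = [
    "NeighborhoodMeasure",
    "TransferencePlan",
    "CurvatureTable",
    "neighborhood_measure",
    "wasserstein1",
    "edge_curvature",
    "compute_all_curvatures",
    "affected_edges",
]


@dataclass(frozen=True)
class NeighborhoodMeasure:
    """Probability measure mu_i over the neighbors of ``center``."""

    center: object
    support: tuple
    masses: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        if len(self.support) != len(m):
            raise ValueError("support and masses length mismatch")
        if m.min() < 0 or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("masses must be non-negative and sum to 1")
        object.__setattr__(self, "masses", m)

    def as_dict(self) -> dict:
        return dict(zip(self.support, self.masses))


@dataclass(frozen=True)
class TransferencePlan:
    """Optimal coupling xi between two neighborhood measures.

    Rows follow ``source.support``, columns ``target.support``; row sums equal
    mu_i, column sums mu_j, and ``cost`` is W1 = sum d(k, l) xi(k, l).
    """

    source: NeighborhoodMeasure
    target: NeighborhoodMeasure
    matrix: np.ndarray
    cost: float


class CurvatureTable:
    """Mapping edge -> kappa with deterministic iteration order.

    ``stale`` flags edges whose value may lag behind the current graph when
    the table is maintained incrementally in local mode.
    """

    def __init__(self, values: dict, stale: set | None = None):
        self._values = {edge_key(*e): float(k) for e, k in values.items()}
        self.stale = set(stale or ())

    def __getitem__(self, e) -> float:
        return self._values[edge_key(*e)]

    def __contains__(self, e) -> bool:
        return edge_key(*e) in self._values

    def __len__(self) -> int:
        return len(self._values)

    def __iter__(self) -> Iterator:
        return iter(self.edges())

    def edges(self) -> list:
        return sorted(
            self._values,
            key=lambda e: (label_sort_key(e[0]), label_sort_key(e[1])),
        )

    def items(self):
        return [(e, self._values[e]) for e in self.edges()]

    def values(self) -> np.ndarray:
        return np.array([self._values[e] for e in self.edges()])

    def min(self):
        """(edge, kappa) with smallest kappa, ties to smallest edge tuple."""
        return min(
            self.items(),
            key=lambda kv: (kv[1], label_sort_key(kv[0][0]), label_sort_key(kv[0][1])),
        )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("u\tv\tkappa\n")
            for (u, v), k in self.items():
                fh.write(f"{u}\t{v}\t{k:.12g}\n")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                [{"u": str(u), "v": str(v), "kappa": k} for (u, v), k in self.items()],
                fh,
                indent=0,
            )
            fh.write("\n")


def neighborhood_measure(g: nx.Graph, i) -> NeighborhoodMeasure:
    """mu_i(k) = rho_ik / sum_{k in N(i)} rho_ik over the neighbors of i."""
    if i not in g:
        raise ValueError(f"vertex {i!r} not in graph")
    nbrs = sorted(g.neighbors(i), key=label_sort_key)
    if not nbrs:
        raise ValueError(f"vertex {i!r} is isolated; no neighborhood measure")
    w = np.array([float(g[i][k].get("weight", 1.0)) for k in nbrs])
    return NeighborhoodMeasure(i, tuple(nbrs), w / w.sum())


def wasserstein1(
    mu_i: NeighborhoodMeasure, mu_j: NeighborhoodMeasure, d: DistanceOracle
) -> TransferencePlan:
    """Exact W1 between two neighborhood measures under the metric ``d``."""
    cost = np.array(
        [[d.distance(k, l) for l in mu_j.support] for k in mu_i.support]
    )
    if not np.all(np.isfinite(cost)):
        raise ValueError("supports span disconnected components (infinite distance)")
    plan, w1 = solve_transport(mu_i.masses, mu_j.masses, cost)
    return TransferencePlan(mu_i, mu_j, plan, w1)


def edge_curvature(g: nx.Graph, e, zero_tol: float = ZERO_TOL_DEFAULT) -> float:
    """kappa(i, j) = 1 - W1(mu_i, mu_j) / d(i, j) for an edge of ``g``."""
    i, j = e
    if not g.has_edge(i, j):
        raise ValueError(f"({i!r}, {j!r}) is not an edge of the graph")
    mu_i = neighborhood_measure(g, i)
    mu_j = neighborhood_measure(g, j)
    d = distances_between(
        g, set(mu_i.support) | {i}, set(mu_j.support) | {j}
    )
    plan = wasserstein1(mu_i, mu_j, d)
    k = 1.0 - plan.cost / d.distance(i, j)
    return 0.0 if abs(k) <= zero_tol else k


def compute_all_curvatures(
    g: nx.Graph, zero_tol: float = ZERO_TOL_DEFAULT
) -> CurvatureTable:
    """Curvature of every edge of ``g`` (deterministic: exact LP per edge)."""
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    eng = CurvatureEngine(g, zero_tol=zero_tol)
    eng.resolve_all()
    return CurvatureTable({eng.label_edge(e): k for e, k in eng.kappa.items()})


def affected_edges(
    g: nx.Graph,
    removed,
    mode: str = "local",
    table: CurvatureTable | None = None,
    zero_tol: float = ZERO_TOL_DEFAULT,
) -> set:
    """Edges to re-examine after ``removed`` was deleted from ``g``.

    ``g`` is the post-removal graph.  In ``local`` mode this is the 2-hop
    incidence rule: every surviving edge with an endpoint in
    {u, v} | N(u) | N(v) (neighborhoods after removal).  In ``exact`` mode
    the whole table is recomputed and the edges whose kappa differs from
    ``table`` (the pre-removal values) are returned.
    """
    u, v = removed
    if g.has_edge(u, v):
        raise ValueError(f"edge ({u!r}, {v!r}) is still present in the graph")
    if mode == "local":
        core = {u, v} | set(g.neighbors(u)) | set(g.neighbors(v))
        return {
            edge_key(s, t) for s in core if s in g for t in g.neighbors(s)
        }
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    if table is None:
        raise ValueError("exact mode needs the pre-removal curvature table")
    fresh = compute_all_curvatures(g, zero_tol=zero_tol)
    return {
        e
        for e in fresh.edges()
        if e not in table or abs(fresh[e] - table[e]) > zero_tol
    }
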