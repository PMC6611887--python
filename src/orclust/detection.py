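"""Curvature-driven divisive community detection.

The detector removes, one per iteration, the most negatively curved edge of
the current graph, recomputes the curvatures that removal can have changed,
and stops as soon as every remaining edge has non-negative curvature (within
a numerical tolerance).  Communities are then the connected components of the
residual graph.  Because bridges between dense regions are the negatively
curved edges, this peels a network apart along its bottlenecks; on sparse,
tree-like structure it deliberately over-fragments, and a preferential-
attachment merge step can re-attach the resulting small components to the
large communities using the curvature of the previously removed edges.

The module is organised like a statsmodels estimator: build an
:class:`OllivierRicciCommunities` model from a graph, call :meth:`fit`, and
read the partition, removal log and diagnostics off the returned
:class:`CommunityDetectionResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._engine import ZERO_TOL_DEFAULT, CurvatureEngine
from .curvature import CurvatureTable
from .graph import (
    label_sort_key,
    read_graph,
    write_partition_json,
    write_partition_tsv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "Partition",
    "OllivierRicciCommunities",
    "CommunityDetectionResults",
    "DetectionResult",
    "detect_communities",
    "components_to_partition",
    "merge_small_communities",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs of the detection loop.

    mode : 'local' recomputes curvature only inside the 2-hop affected zone
        of each removal (with a final verification sweep); 'exact' reproduces
        full per-iteration recomputation; 'endpoint' recomputes only edges
        incident to the removed endpoints and never settles stale values (the
        narrowest reading of local recomputation).
    epsilon : values within epsilon of zero count as non-negative, so LP
        round-off cannot create phantom negative edges.
    merge : 'none', 'min_size_fraction' (communities smaller than
        ``min_size_fraction`` of the vertex count are re-attached) or
        'target_count' (merge until ``target_count`` communities remain).
    seed : unused by the deterministic core loop; reserved.
    """

    mode: str = "local"
    epsilon: float = ZERO_TOL_DEFAULT
    merge: str = "none"
    min_size_fraction: float = 0.01
    target_count: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("local", "exact", "endpoint"):
            raise ValueError(
                f"mode must be 'local', 'exact' or 'endpoint', got {self.mode!r}"
            )
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.merge not in ("none", "min_size_fraction", "target_count"):
            raise ValueError(f"unknown merge policy {self.merge!r}")
        if self.merge == "min_size_fraction" and not (0 < self.min_size_fraction < 1):
            raise ValueError("min_size_fraction must be in (0, 1)")
        if self.merge == "target_count" and (
            self.target_count is None or self.target_count < 1
        ):
            raise ValueError("target_count must be >= 1")


class Partition:
    """Assignment of every vertex to exactly one community.

    Community ids are dense integers 0..C-1, ordered by descending community
    size with ties broken by the smallest member label.
    """

    def __init__(self, groups):
        """``groups``: iterable of vertex collections (pairwise disjoint)."""
        sets = [sorted(g, key=label_sort_key) for g in groups if len(g) > 0]
        seen: set = set()
        for s in sets:
            for v in s:
                if v in seen:
                    raise ValueError(f"vertex {v!r} assigned to two communities")
                seen.add(v)
        sets.sort(key=lambda s: (-len(s), [label_sort_key(v) for v in s]))
        self._sets = [tuple(s) for s in sets]
        self._assign = {v: c for c, s in enumerate(self._sets) for v in s}

    @classmethod
    def from_assignment(cls, assignment: dict) -> "Partition":
        groups: dict = {}
        for v, c in assignment.items():
            groups.setdefault(c, []).append(v)
        return cls(groups.values())

    @property
    def n_communities(self) -> int:
        return len(self._sets)

    @property
    def sizes(self) -> list:
        return [len(s) for s in self._sets]

    def community_of(self, v) -> int:
        return self._assign[v]

    def __getitem__(self, v) -> int:
        return self._assign[v]

    def members(self, c: int) -> tuple:
        return self._sets[c]

    def to_sets(self) -> list:
        return [frozenset(s) for s in self._sets]

    def to_dict(self) -> dict:
        return dict(self._assign)

    @property
    def vertices(self) -> set:
        return set(self._assign)

    def __len__(self) -> int:
        return len(self._assign)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return set(self.to_sets()) == set(other.to_sets())

    def __repr__(self) -> str:
        return f"Partition({self.n_communities} communities, sizes={self.sizes})"

    def to_tsv(self, path: str) -> None:
        write_partition_tsv(self._assign, path)

    def to_json(self, path: str) -> None:
        write_partition_json(self._assign, path)


def components_to_partition(g: nx.Graph) -> Partition:
    """One community per connected component (isolated vertex = singleton)."""
    return Partition(nx.connected_components(g))


class OllivierRicciCommunities:
    """Curvature-based community-identification model for one graph.

    Parameters
    ----------
    graph : undirected simple ``networkx.Graph`` with positive edge weights
        (missing ``weight`` attributes count as 1).
    config : optional :class:`DetectionConfig`; keyword arguments override
        individual fields.

    Examples
    --------
    >>> import networkx as nx
    >>> from orclust import OllivierRicciCommunities
    >>> g = nx.barbell_graph(5, 0)
    >>> res = OllivierRicciCommunities(g).fit()
    >>> res.partition.n_communities
    2
    """

    def __init__(self, graph: nx.Graph, config: DetectionConfig | None = None, **kw):
        if config is None:
            config = DetectionConfig(**kw)
        elif kw:
            raise TypeError("pass either a config object or keyword fields, not both")
        self.graph = graph
        self.config = config

    @classmethod
    def from_file(cls, path: str, format: str = "edgelist", **kw):
        return cls(read_graph(path, format=format), **kw)

    def fit(self) -> "CommunityDetectionResults":
        g = self.graph
        cfg = self.config
        eps = cfg.epsilon
        removal_log: list = []
        if g.number_of_edges() == 0:
            residual = g.copy()
            pre = components_to_partition(residual)
            return CommunityDetectionResults(
                self, residual, pre, pre, removal_log, CurvatureTable({})
            )
        eng = CurvatureEngine(g, zero_tol=eps)
        max_iter = g.number_of_edges()
        it = 0
        while True:
            e, k = eng.min_edge()
            if e is None or k >= -eps:
                # local mode can leave distance-mediated updates outside the
                # 2-hop zone unapplied; settle them before accepting the stop
                if eng.has_deferred:
                    eng.flush_stale()
                    e, k = eng.min_edge()
                    if e is not None and k < -eps:
                        continue
                break
            if it >= max_iter:  # pragma: no cover - each step drops one edge
                raise RuntimeError("detection loop exceeded |E| iterations")
            it += 1
            u, v = eng.label_edge(e)
            removal_log.append((u, v, k))
            logger.debug("iteration %d: removing (%r, %r) kappa=%.6f", it, u, v, k)
            eng.remove_edge(*e, mode=cfg.mode)
        residual = g.copy()
        residual.remove_edges_from([(u, v) for u, v, _ in removal_log])
        pre_merge = components_to_partition(residual)
        eng.resolve_all()
        stale_edges = set()
        if cfg.mode == "endpoint":
            # endpoint mode never settles out-of-zone changes; report which
            # residual values may lag behind the final graph
            fresh = CurvatureEngine(residual, zero_tol=eps)
            fresh.resolve_all()
            stale_edges = {
                fresh.label_edge(e)
                for e, kk in fresh.kappa.items()
                if kk != eng.kappa.get(e)
            }
        final_table = CurvatureTable(
            {eng.label_edge(e): kk for e, kk in eng.kappa.items()},
            stale=stale_edges,
        )
        results = CommunityDetectionResults(
            self, residual, pre_merge, pre_merge, removal_log, final_table
        )
        if cfg.merge != "none":
            results.partition = merge_small_communities(g, results, cfg)
        logger.info(
            "removed %d edges; %d communities%s",
            len(removal_log),
            results.partition.n_communities,
            "" if cfg.merge == "none" else f" after {cfg.merge} merging",
        )
        return results


class CommunityDetectionResults:
    """Outcome of a detection run.

    Attributes
    ----------
    partition : final :class:`Partition` (after any merging).
    pre_merge_partition : connected components of the residual graph before
        merging.
    removal_log : ``pandas.DataFrame`` with columns step, u, v, kappa — the
        order in which edges were removed and their curvature at removal.
    curvatures : :class:`CurvatureTable` of the residual graph at the stop.
    residual_graph : the input graph minus the removed edges.
    """

    def __init__(self, model, residual, partition, pre_merge, removal_log, table):
        self.model = model
        self.residual_graph = residual
        self.partition = partition
        self.pre_merge_partition = pre_merge
        self._removals = list(removal_log)
        self.curvatures = table

    @property
    def removal_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": s, "u": u, "v": v, "kappa": k}
                for s, (u, v, k) in enumerate(self._removals, start=1)
            ],
            columns=["step", "u", "v", "kappa"],
        )

    @property
    def removed_edges(self) -> list:
        return [(u, v, k) for u, v, k in self._removals]

    @property
    def n_communities(self) -> int:
        return self.partition.n_communities

    @property
    def community_sizes(self) -> list:
        return self.partition.sizes

    def summary(self) -> str:
        g = self.model.graph
        cfg = self.model.config
        lines = [
            "Ollivier-Ricci community identification",
            "=" * 47,
            f"vertices:            {g.number_of_nodes()}",
            f"edges:               {g.number_of_edges()}",
            f"mode:                {cfg.mode}",
            f"epsilon:             {cfg.epsilon:g}",
            f"edges removed:       {len(self._removals)}",
            f"communities (pre):   {self.pre_merge_partition.n_communities}",
            f"merge policy:        {cfg.merge}",
            f"communities (final): {self.partition.n_communities}",
            f"community sizes:     {self.partition.sizes}",
        ]
        if self._removals:
            ks = np.array([k for _, _, k in self._removals])
            lines.append(
                f"removed-edge kappa:  min {ks.min():.4f}  "
                f"mean {ks.mean():.4f}  max {ks.max():.4f}"
            )
        return "\n".join(lines)

    def removal_log_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("step\tu\tv\tkappa\n")
            for s, (u, v, k) in enumerate(self._removals, start=1):
                fh.write(f"{s}\t{u}\t{v}\t{k:.12g}\n")

    def plot_curvature_histogram(self, ax=None, bins=30):
        """Histogram of residual-edge curvatures plus removed-edge curvatures."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        resid = self.curvatures.values()
        if len(resid):
            ax.hist(resid, bins=bins, alpha=0.6, label="residual edges")
        if self._removals:
            ax.hist(
                [k for _, _, k in self._removals],
                bins=bins,
                alpha=0.6,
                label="removed edges",
            )
        ax.set_xlabel("edge Ollivier-Ricci curvature")
        ax.set_ylabel("count")
        ax.legend()
        return ax


# back-compat style alias: the results object is the detection result record
DetectionResult = CommunityDetectionResults


def detect_communities(
    g: nx.Graph, config: DetectionConfig | None = None, **kw
) -> CommunityDetectionResults:
    """Run the full detection loop; functional facade over the model class."""
    return OllivierRicciCommunities(g, config=config, **kw).fit()


def merge_small_communities(
    g_original: nx.Graph,
    result: CommunityDetectionResults,
    config: DetectionConfig,
) -> Partition:
    """Preferential attachment of small residual communities.

    Every community below the size threshold (or beyond the target count) is
    re-attached, smallest first, to the retained community with the highest
    attachment score: the arithmetic mean of the at-removal curvature over
    the removed edges joining the small community to that candidate.  Ties go
    to the larger candidate, then the smaller community id.  Small
    communities with no removed edge into any retained community are left in
    place with a logged warning.
    """
    part = result.pre_merge_partition
    removed = result.removed_edges
    n_vertices = len(part)
    groups: dict = {c: set(part.members(c)) for c in range(part.n_communities)}
    assign = {v: c for c, mem in groups.items() for v in mem}

    if config.merge == "min_size_fraction":
        threshold = config.min_size_fraction * n_vertices
        retained = {c for c, mem in groups.items() if len(mem) >= threshold}

        def small_ids():
            return [c for c in groups if c not in retained]

        def done():
            return not small_ids()

    elif config.merge == "target_count":
        order = sorted(groups, key=lambda c: (-len(groups[c]), c))
        retained = set(order[: config.target_count])

        def small_ids():
            return [c for c in groups if c not in retained]

        def done():
            return len(groups) <= config.target_count

    else:
        return result.pre_merge_partition

    unmergeable: set = set()
    while not done():
        candidates = [c for c in small_ids() if c not in unmergeable]
        if not candidates:
            break
        c = min(candidates, key=lambda c: (len(groups[c]), c))
        scores: dict = {}
        for u, v, k in removed:
            cu, cv = assign[u], assign[v]
            if cu == c and cv in retained:
                scores.setdefault(cv, []).append(k)
            elif cv == c and cu in retained:
                scores.setdefault(cu, []).append(k)
        if not scores:
            logger.warning(
                "community %d (size %d) has no removed edge into a retained "
                "community; left unmerged",
                c,
                len(groups[c]),
            )
            unmergeable.add(c)
            continue
        best = max(
            scores,
            key=lambda r: (float(np.mean(scores[r])), len(groups[r]), -r),
        )
        for v in groups[c]:
            assign[v] = best
        groups[best] |= groups.pop(c)
        # a merge can connect previously unmergeable communities to a
        # retained host through the absorbed vertices; retry them
        unmergeable.clear()
    return Partition(groups.values())
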