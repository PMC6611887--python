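"""Graph data model, file I/O and shortest-path services.

Graphs are plain :class:`networkx.Graph` objects: undirected, simple, with a
positive ``weight`` attribute per edge (1.0 for unweighted input).  Vertex
labels are opaque and preserved verbatim; every deterministic ordering in the
package sorts labels with :func:`label_sort_key`.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Hashable, Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "GraphFormat",
    "read_graph",
    "write_graph",
    "largest_component",
    "distances_between",
    "DistanceOracle",
    "label_sort_key",
    "validate_graph",
]

_FORMATS = ("edgelist", "gml", "graphml")


def label_sort_key(label: Hashable):
    """Total order over vertex labels used for all deterministic tie-breaks.

    Numeric labels sort numerically, everything else lexicographically by its
    string form; mixed collections are ordered numbers-first.
    """
    if isinstance(label, bool):
        return (1, str(label))
    if isinstance(label, (int, float)):
        return (0, float(label), str(label))
    return (1, str(label))


def edge_key(u, v):
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if label_sort_key(u) <= label_sort_key(v) else (v, u)


class GraphFormat:
    EDGELIST = "edgelist"
    GML = "gml"
    GRAPHML = "graphml"


def _parse_edgelist(path: str) -> nx.DiGraph:
    g = nx.DiGraph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 'src dst [weight]', got {raw!r}"
                )
            u, v = parts[0], parts[1]
            w = float(parts[2]) if len(parts) == 3 else 1.0
            if g.has_edge(u, v):
                w = max(w, g[u][v]["weight"])
            g.add_edge(u, v, weight=w)
    return g


def _as_simple_undirected(g) -> nx.Graph:
    """Symmetrize/simplify raw parsed input (max weight on conflicts)."""
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    n_loops = 0
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        if u == v:
            n_loops += 1
            continue
        if out.has_edge(u, v):
            w = max(w, out[u][v]["weight"])
        out.add_edge(u, v, weight=w)
    if n_loops:
        logger.warning("dropped %d self-loop(s) on read", n_loops)
    return out


def validate_graph(g: nx.Graph) -> None:
    """Check the weighted-graph invariants; raise ``ValueError`` on failure."""
    if g.is_directed() or g.is_multigraph():
        raise ValueError("graph must be a simple undirected networkx.Graph")
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        if not (w > 0):
            raise ValueError(f"non-positive weight {w!r} on edge ({u!r}, {v!r})")
        if u == v:
            raise ValueError(f"self-loop at vertex {u!r}")


def read_graph(path: str, format: str = "edgelist") -> nx.Graph:
    """Read an undirected weighted graph from ``path``.

    Directed input is symmetrized (max weight when both directions carry a
    weight), duplicate edges are collapsed, self-loops are dropped with a
    logged warning, and missing weights default to 1.0.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "edgelist":
        raw = _parse_edgelist(path)
    elif format == "gml":
        raw = nx.read_gml(path)
    else:
        raw = nx.read_graphml(path)
    g = _as_simple_undirected(raw)
    validate_graph(g)
    return g


def write_graph(g: nx.Graph, path: str, format: str = "edgelist") -> None:
    """Write a graph so that :func:`read_graph` round-trips it."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    validate_graph(g)
    if format == "edgelist":
        with open(path, "w") as fh:
            for u, v in sorted(
                (edge_key(u, v) for u, v in g.edges()),
                key=lambda e: (label_sort_key(e[0]), label_sort_key(e[1])),
            ):
                w = g[u][v].get("weight", 1.0)
                fh.write(f"{u} {v} {w!r}\n")
    elif format == "gml":
        nx.write_gml(g, path)
    else:
        nx.write_graphml(g, path)


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the smallest sorted vertex-label sequence.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no largest component")
    comps = [sorted(c, key=label_sort_key) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), [label_sort_key(x) for x in c]))
    return g.subgraph(comps[0]).copy()


class DistanceOracle:
    """Exact shortest-path distances for a set of (source, target) pairs.

    Edge weights are used as lengths (hop count when every weight is 1).
    ``inf`` is recorded for pairs in different components.
    """

    def __init__(self, dist: dict):
        self._dist = dist

    def distance(self, u, v) -> float:
        try:
            return self._dist[(u, v)]
        except KeyError:
            try:
                return self._dist[(v, u)]
            except KeyError:
                raise KeyError(f"distance for pair ({u!r}, {v!r}) was not requested")

    def __call__(self, u, v) -> float:
        return self.distance(u, v)

    def items(self):
        return self._dist.items()


def distances_between(
    g: nx.Graph, sources: Iterable, targets: Iterable
) -> DistanceOracle:
    """Shortest-path distances restricted to ``sources`` x ``targets``."""
    sources = list(sources)
    targets = set(targets)
    for x in list(sources) + list(targets):
        if x not in g:
            raise ValueError(f"vertex {x!r} not in graph")
    dist: dict = {}
    for s in sources:
        lengths = nx.single_source_dijkstra_path_length(g, s, weight="weight")
        for t in targets:
            dist[(s, t)] = float(lengths.get(t, float("inf")))
    return DistanceOracle(dist)


def write_partition_tsv(assignment: dict, path: str) -> None:
    """Two-column TSV ``vertex<TAB>community_id``."""
    with open(path, "w") as fh:
        for v in sorted(assignment, key=label_sort_key):
            fh.write(f"{v}\t{assignment[v]}\n")


def write_partition_json(assignment: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({str(v): int(c) for v, c in assignment.items()}, fh, indent=0)
        fh.write("\n")
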