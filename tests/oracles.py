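"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own transport solver:
Floyd-Warshall for distances, unit-mass replication + the Hungarian
algorithm or extreme-point enumeration for W1, and permutation search for
partition matching.
"""

from __future__ import annotations

import itertools
from math import inf, lcm

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment


def floyd_warshall(g: nx.Graph) -> dict:
    nodes = list(g.nodes())
    d = {(u, v): 0.0 if u == v else inf for u in nodes for v in nodes}
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        d[(u, v)] = min(d[(u, v)], w)
        d[(v, u)] = min(d[(v, u)], w)
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[(i, k)] + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = d[(i, k)] + d[(k, j)]
    return d


def w1_uniform_assignment(cost: np.ndarray) -> float:
    """W1 between uniform measures by unit replication + Hungarian solve.

    Each of the n sources carries 1/n, each of the m sinks 1/m; replicating
    sources L/n times and sinks L/m times (L = lcm(n, m)) turns the
    transportation problem into an L x L assignment problem whose optimum,
    divided by L, is exactly W1.
    """
    n, m = cost.shape
    L = lcm(n, m)
    rows = np.repeat(np.arange(n), L // n)
    cols = np.repeat(np.arange(m), L // m)
    big = cost[np.ix_(rows, cols)]
    r, c = linear_sum_assignment(big)
    return float(big[r, c].sum()) / L


def w1_extreme_points(a: np.ndarray, b: np.ndarray, cost: np.ndarray) -> float:
    """W1 by enumerating every basic feasible plan (spanning-tree bases).

    Exponential; only sensible for supports of size <= 4.  Every extreme
    point of the transportation polytope is supported on a spanning tree of
    the complete bipartite graph, so enumerating all n+m-1 cell subsets that
    form a tree and solving each by leaf elimination visits every vertex of
    the polytope.
    """
    n, m = len(a), len(b)
    cells = list(itertools.product(range(n), range(m)))
    best = inf
    for basis in itertools.combinations(cells, n + m - 1):
        flows = _tree_flows(a, b, basis, n, m)
        if flows is None:
            continue
        if min(flows.values()) < -1e-12:
            continue
        val = sum(f * cost[k, l] for (k, l), f in flows.items())
        best = min(best, val)
    return best


def _tree_flows(a, b, basis, n, m):
    """Unique flow on a spanning-tree basis via leaf elimination."""
    supply = {("r", k): float(a[k]) for k in range(n)}
    supply.update({("c", l): -float(b[l]) for l in range(m)})
    inc: dict = {node: set() for node in supply}
    for k, l in basis:
        inc[("r", k)].add((k, l))
        inc[("c", l)].add((k, l))
    flows = {}
    remaining = set(basis)
    while remaining:
        leaf = None
        for node, edges in inc.items():
            live = edges & remaining
            if len(live) == 1:
                leaf = (node, next(iter(live)))
                break
        if leaf is None:
            return None  # basis contains a cycle
        node, cell = leaf
        k, l = cell
        f = supply[node] if node[0] == "r" else -supply[node]
        flows[cell] = f
        supply[("r", k)] -= f
        supply[("c", l)] += f
        remaining.discard(cell)
    if any(abs(s) > 1e-9 for s in supply.values()):
        return None  # basis spans a disconnected forest
    return flows


def misclassified_bruteforce(pred_sets, truth_sets, n_vertices) -> int:
    """Minimum misassigned vertices over all one-to-one matchings."""
    P, T = list(pred_sets), list(truth_sets)
    if len(P) < len(T):
        P, T = T, P  # search over injections of the smaller side
    best = 0
    for perm in itertools.permutations(range(len(P)), len(T)):
        overlap = sum(len(P[p] & T[t]) for t, p in enumerate(perm))
        best = max(best, overlap)
    return n_vertices - best


def lp_curvature(g: nx.Graph, u, v) -> float:
    """Edge curvature via scipy's HiGHS LP — library reference route."""
    from orclust._transport import linprog_transport

    sp = floyd_warshall(g)
    nu = sorted(g.neighbors(u), key=str)
    nv = sorted(g.neighbors(v), key=str)
    wa = np.array([float(g[u][x].get("weight", 1.0)) for x in nu])
    wb = np.array([float(g[v][x].get("weight", 1.0)) for x in nv])
    C = np.array([[sp[(x, y)] for y in nv] for x in nu])
    _, w1 = linprog_transport(wa / wa.sum(), wb / wb.sum(), C)
    return 1.0 - w1 / sp[(u, v)]
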