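"""Incremental edge-curvature engine used by the detection loop.

Vertices are re-indexed 0..n-1 in label-sort order, so index tuples compare
exactly like label-lexicographic edge tuples.  The engine keeps

* a dense weight matrix ``W`` of the *current* graph,
* the all-pairs shortest-path matrix ``D`` of the current graph,
* a ``kappa`` table over the current edge set.

Four ideas keep the removal loop fast without changing any value the loop
acts on:

1. Metric reduction of each transport problem.  Shortest-path costs satisfy
   the triangle inequality, so an optimal plan exists in which every vertex
   common to both neighborhoods keeps min(mu_i(x), mu_j(x)) of its mass in
   place at zero cost; only the residual mass is handed to the LP solver.
2. Restricted all-pairs updates.  After removing (u, v), a vertex's distance
   row can change only if its old shortest path to u or v ran through the
   removed edge; only those rows are re-solved (scipy.sparse.csgraph).
3. Pair-precision recomputation.  An edge's curvature depends on its two
   endpoint measures and the distance block between its neighborhoods; a
   per-edge signature of those inputs is cached, and the edge is re-examined
   only when the signature actually changed.
4. Lazy exact evaluation.  Any feasible transport plan upper-bounds W1 and
   therefore lower-bounds kappa, so a re-examined edge first receives a
   cheap greedy-plan bound.  The minimum search resolves bounds to exact LP
   optima until the minimum is exact, which yields the same removal sequence
   and the same stopping decision as eager recomputation: every value the
   loop compares or logs is an exact optimum, and a lower bound that stays
   above the threshold proves the edge could not have been selected.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._transport import greedy_transport_bound, solve_transport
from .graph import label_sort_key

ZERO_TOL_DEFAULT = 1e-9

#: recomputation scopes after one edge removal
MODES = ("local", "exact", "endpoint")

_EMPTY = np.empty(0, dtype=np.int64)
_EMPTYF = np.empty(0)


def _reduced_problem(a, b, C, pos_a, pos_b, ga=None, gb=None):
    """Cancel shared atoms along the zero-cost diagonal of a metric cost.

    Returns (a', b', C', ga', gb') of the residual problem — ``ga``/``gb``
    carry global vertex ids through the reduction — or None when the
    measures coincide (W1 = 0).
    """
    if ga is None:
        ga = np.arange(len(a))
    if gb is None:
        gb = np.arange(len(b))
    if len(pos_a):
        a = a.copy()
        b = b.copy()
        m = np.minimum(a[pos_a], b[pos_b])
        a[pos_a] -= m
        b[pos_b] -= m
    ra = np.flatnonzero(a > 1e-15)
    rb = np.flatnonzero(b > 1e-15)
    if len(ra) == 0 or len(rb) == 0:
        return None
    aa = a[ra]
    bb = b[rb]
    # rebalance round-off so the reduced problem stays exactly balanced
    diff = aa.sum() - bb.sum()
    if diff > 0:
        bb[np.argmax(bb)] += diff
    elif diff < 0:
        aa[np.argmax(aa)] -= diff
    return aa, bb, C[np.ix_(ra, rb)], ga[ra], gb[rb]


def metric_reduced_w1(a, b, C, pos_a=None, pos_b=None):
    """Exact W1 for metric costs, pre-matching shared atoms at zero cost."""
    if pos_a is None:
        pos_a = pos_b = np.empty(0, dtype=np.int64)
    red = _reduced_problem(a, b, C, pos_a, pos_b)
    if red is None:
        return 0.0
    return solve_transport(red[0], red[1], red[2])[1]


class CurvatureEngine:
    def __init__(self, graph, zero_tol: float = ZERO_TOL_DEFAULT):
        self.zero_tol = float(zero_tol)
        self.labels = sorted(graph.nodes(), key=label_sort_key)
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        self.n = n
        self.W = np.zeros((n, n))
        for u, v, data in graph.edges(data=True):
            w = float(data.get("weight", 1.0))
            i, j = self.index[u], self.index[v]
            self.W[i, j] = self.W[j, i] = w
        self.unweighted = bool(np.all((self.W == 0) | (self.W == 1)))
        self.nbrs = [set(np.flatnonzero(self.W[i]).tolist()) for i in range(n)]
        self._nbr_arr: list = [None] * n  # cached sorted neighbor arrays
        self.D = self._apsp()
        self.kappa: dict = {}
        self.exact: set = set()
        self._sig: dict = {}
        self._heap: list = []  # lazy (kappa, edge) min-queue
        # last feasible transport plan per edge, in global vertex indices
        # (residual part only; pre-matched shared atoms ride at zero cost)
        self._plan: dict = {}
        # local mode defers out-of-zone change detection to one final sweep
        self._deferred = False
        for i in range(n):
            for j in self.nbrs[i]:
                if i < j:
                    self._examine((i, j))

    # -- internals ---------------------------------------------------------

    def _csgraph(self):
        return csr_matrix(self.W)

    def _apsp(self) -> np.ndarray:
        if self.unweighted:
            return shortest_path(self._csgraph(), method="D", unweighted=True)
        return shortest_path(self._csgraph(), method="D")

    def _nbr(self, i) -> np.ndarray:
        arr = self._nbr_arr[i]
        if arr is None:
            arr = np.fromiter(
                sorted(self.nbrs[i]), dtype=np.int64, count=len(self.nbrs[i])
            )
            self._nbr_arr[i] = arr
        return arr

    def _edge_inputs(self, i, j):
        na = self._nbr(i)
        nb = self._nbr(j)
        cost = self.D.take((na[:, None] * self.n + nb).ravel()).reshape(
            len(na), len(nb)
        )
        return na, nb, cost

    def _problem(self, i, j, na, nb, cost):
        wa = self.W[i, na]
        wb = self.W[j, nb]
        mu_i = wa / wa.sum()
        mu_j = wb / wb.sum()
        # shared atoms sit on a zero-cost diagonal of the metric cost block
        _, pos_a, pos_b = np.intersect1d(
            na, nb, assume_unique=True, return_indices=True
        )
        return _reduced_problem(mu_i, mu_j, cost, pos_a, pos_b, na, nb)

    def _examine(self, e):
        """Fully re-evaluate an edge: reduce, then greedy bound or exact."""
        i, j = e
        na, nb, cost = self._edge_inputs(i, j)
        dij = self.D[i, j]
        self._sig[e] = hash((na.tobytes(), nb.tobytes(), cost.tobytes(), dij))
        red = self._problem(i, j, na, nb, cost)
        if red is None:
            self._plan[e] = (_EMPTY, _EMPTY, _EMPTYF)  # W1 = 0 exactly
            self._store(e, 1.0, True)
            return
        aa, bb, Cr, ga, gb = red
        # tiny residuals: the exact solve is as cheap as the bound
        if aa.shape[0] * bb.shape[0] <= 16:
            plan, w1 = solve_transport(aa, bb, Cr)
            self._keep_plan(e, plan, ga, gb)
            self._store(e, self._snap(1.0 - w1 / dij), True)
            return
        ub, rows, cols, amts = greedy_transport_bound(aa, bb, Cr)
        self._plan[e] = (ga[rows], gb[cols], amts)
        # small slack keeps the bound valid under round-off
        self._store(e, 1.0 - ub / dij - 1e-12, False)

    def _reexamine_fast(self, e):
        """Refresh an edge's lower bound by re-costing its cached plan.

        The cached plan has the current marginals (measures change only for
        edges incident to a removal, which are fully re-examined instead), so
        it stays feasible and its cost under the current distances is a valid
        upper bound on W1.
        """
        gk, gl, vals = self._plan[e]
        w1_ub = float(vals @ self.D[gk, gl]) if len(vals) else 0.0
        self._store(e, 1.0 - w1_ub / self.D[e[0], e[1]] - 1e-12, False)

    def _resolve(self, e):
        """Replace a bound with the exact LP optimum."""
        i, j = e
        na, nb, cost = self._edge_inputs(i, j)
        dij = self.D[i, j]
        red = self._problem(i, j, na, nb, cost)
        if red is None:
            w1 = 0.0
            self._plan[e] = (_EMPTY, _EMPTY, _EMPTYF)
        else:
            aa, bb, Cr, ga, gb = red
            plan, w1 = solve_transport(aa, bb, Cr)
            self._keep_plan(e, plan, ga, gb)
        self._store(e, self._snap(1.0 - w1 / dij), True)

    def _keep_plan(self, e, plan, ga, gb):
        rows, cols = np.nonzero(plan > 1e-15)
        self._plan[e] = (ga[rows], gb[cols], plan[rows, cols])

    def _store(self, e, value: float, is_exact: bool) -> None:
        self.kappa[e] = value
        if is_exact:
            self.exact.add(e)
        else:
            self.exact.discard(e)
        heapq.heappush(self._heap, (value, e))
        if len(self._heap) > 4 * len(self.kappa) + 1024:
            self._heap = [(v, ee) for ee, v in self.kappa.items()]
            heapq.heapify(self._heap)

    def _snap(self, k: float) -> float:
        if abs(k) <= self.zero_tol:
            return 0.0
        # snap to a 1e-12 grid so mathematically equal curvatures compare
        # equal and the lexicographic tie-break is deterministic
        return round(k, 12)

    # -- public ------------------------------------------------------------

    def edges(self):
        return self.kappa.keys()

    def resolve_all(self) -> None:
        """Make every stored curvature an exact LP optimum."""
        for e in sorted(set(self.kappa) - self.exact):
            self._resolve(e)

    def min_edge(self):
        """(edge, kappa) with the smallest exact kappa.

        Lower bounds encountered during the search are resolved to exact
        values, so the returned minimum is the true one and ties break on
        the smallest index tuple.
        """
        while True:
            if not self.kappa:
                return None, None
            if not self._heap:
                self._heap = [(v, ee) for ee, v in self.kappa.items()]
                heapq.heapify(self._heap)
            v, e = self._heap[0]
            if e not in self.kappa or self.kappa[e] != v:
                heapq.heappop(self._heap)  # stale entry
                continue
            if e in self.exact:
                return e, v
            self._resolve(e)

    def remove_edge(self, i, j, mode: str = "local"):
        """Remove edge, refresh distances, re-examine dependent curvatures.

        ``local`` limits per-removal re-examination to the 2-hop affected
        zone around the removal (endpoints, their neighbors, and edges
        touching those); changes outside that zone are settled later by
        :meth:`flush_stale`.  ``exact`` re-examines every edge whose inputs
        changed anywhere in the graph, reproducing full per-iteration
        recomputation.  ``endpoint`` re-examines only the edges incident to
        the removed endpoints and tracks nothing else (the narrowest reading
        of local recomputation; values elsewhere are allowed to go stale).
        """
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        if i > j:
            i, j = j, i
        del self.kappa[(i, j)]
        self.exact.discard((i, j))
        self._sig.pop((i, j), None)
        self._plan.pop((i, j), None)
        w_uv = self.W[i, j]
        self.W[i, j] = self.W[j, i] = 0.0
        self.nbrs[i].discard(j)
        self.nbrs[j].discard(i)
        self._nbr_arr[i] = self._nbr_arr[j] = None

        # rows whose old shortest path to i or j could have used the edge
        col_i = self.D[:, i]
        col_j = self.D[:, j]
        with np.errstate(invalid="ignore"):
            maybe = (np.abs(col_i + w_uv - col_j) <= 1e-12) | (
                np.abs(col_j + w_uv - col_i) <= 1e-12
            )
        maybe[i] = maybe[j] = True
        src = np.flatnonzero(maybe)
        if self.unweighted:
            rows = shortest_path(
                self._csgraph(), method="D", unweighted=True, indices=src
            )
        else:
            rows = shortest_path(self._csgraph(), method="D", indices=src)
        with np.errstate(invalid="ignore"):
            row_changed = np.any(rows != self.D[src], axis=1)
        changed = src[row_changed]
        self.D[src] = rows
        self.D[:, src] = rows.T

        incident = {
            (min(a, b), max(a, b)) for a in (i, j) for b in self.nbrs[a]
        }
        if mode == "endpoint":
            candidates: set = set()
        else:
            # an edge's cost block can change only if both endpoints touch a
            # changed distance row (sound vertex-level necessary condition)
            flagged = np.zeros(self.n, dtype=bool)
            flagged[changed] = True
            for x in changed:
                flagged[self._nbr(x)] = True
            if mode == "local":
                # restrict per-removal work to the 2-hop affected zone and
                # settle everything else in the final sweep
                if changed.size:
                    self._deferred = True
                two_hop = {i, j} | self.nbrs[i] | self.nbrs[j]
                candidates = {
                    (min(s, t), max(s, t))
                    for s in two_hop
                    if flagged[s]
                    for t in self.nbrs[s]
                    if flagged[t]
                }
            else:
                flag_idx = np.flatnonzero(flagged)
                candidates = set()
                for x in flag_idx:
                    for y in self.nbrs[x]:
                        if flagged[y] and x < y:
                            candidates.add((x, y))
            candidates -= incident
        for e in sorted(incident):
            self._examine(e)
        for e in sorted(candidates):
            self._reexamine_fast(e)

    @property
    def has_deferred(self) -> bool:
        return self._deferred

    def flush_stale(self) -> bool:
        """Settle changes deferred by local mode; True if any value moved.

        One signature sweep over the surviving edges re-examines exactly
        those whose inputs changed since they were last evaluated.
        """
        any_change = False
        for e in sorted(self.kappa):
            na, nb, cost = self._edge_inputs(*e)
            sig = hash(
                (na.tobytes(), nb.tobytes(), cost.tobytes(), self.D[e[0], e[1]])
            )
            if sig != self._sig.get(e):
                old = self.kappa[e]
                was_exact = e in self.exact
                self._examine(e)
                if self.kappa[e] != old or was_exact:
                    any_change = True
        self._deferred = False
        return any_change

    def label_edge(self, e):
        return (self.labels[e[0]], self.labels[e[1]])
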