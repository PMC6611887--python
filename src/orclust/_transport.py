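"""Exact solvers for the transportation linear program behind W1.

The Wasserstein-1 distance between two discrete neighborhood measures is the
optimum of the balanced transportation LP

    min  sum_{k,l} d(k,l) xi(k,l)
    s.t. sum_l xi(k,l) = mu_i(k),  sum_k xi(k,l) = mu_j(l),  xi >= 0.

Problems arising from graph neighborhoods are small (supports of a few dozen
points) but are solved millions of times during a detection run, so the
default path is a numba-compiled successive-shortest-path (SSP) min-cost-flow
solver: a Dial bucket-queue variant for integer costs (hop distances) and a
scan-min Dijkstra variant for float costs (weighted distances).  Both maintain
node potentials, so every augmentation is along a cheapest residual path and
the final flow is an exact LP optimum.  Each solution is certified a
posteriori against the LP dual; any failure (or numba being unavailable)
falls back to ``scipy.optimize.linprog`` (HiGHS).
"""

from __future__ import annotations

import numpy as np

__all__ = ["solve_transport", "linprog_transport"]

_FEAS_TOL = 1e-9

try:  # pragma: no cover - numba is a hard dependency, guard is belt-and-braces
    import numba
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_INF64 = np.int64(1) << np.int64(60)
_INF = 1e18


if _HAVE_NUMBA:

    @njit(cache=True)
    def _ssp_int(a, b, Ci, nbuckets):
        """SSP with Dial bucket queue; integer costs.

        Returns (flow, potentials, status); status 0 = converged,
        -1 = bucket overflow (retry with more buckets), -2/-3 = stuck
        (caller must fall back to the LP solver).
        """
        n = a.shape[0]
        m = b.shape[0]
        N = n + m
        flow = np.zeros((n, m))
        pot = np.zeros(N, np.int64)
        supply = a.copy()
        demand = b.copy()
        total = supply.sum()
        eps = 1e-12 * max(1.0, total)
        dist = np.empty(N, np.int64)
        visited = np.empty(N, numba.boolean)
        parent = np.empty(N, np.int64)
        bhead = np.empty(nbuckets, np.int64)
        # entry pool: a node may sit in several buckets at once, so every
        # insertion gets its own pool slot (a per-node next pointer corrupts
        # the earlier bucket's chain)
        cap = 4 * (n * m + N) + 16
        enode = np.empty(cap, np.int64)
        enext = np.empty(cap, np.int64)
        guard = 0
        maxit = 16 * N * N + 1000
        while total > eps:
            guard += 1
            if guard > maxit:
                return flow, pot.astype(np.float64), -3.0
            for x in range(N):
                dist[x] = _INF64
                visited[x] = False
                parent[x] = -1
            for q in range(nbuckets):
                bhead[q] = -1
            ne = 0
            for i in range(n):
                if supply[i] > eps:
                    dist[i] = 0
                    enode[ne] = i
                    enext[ne] = bhead[0]
                    bhead[0] = ne
                    ne += 1
            t_best = -1
            cur = 0
            while cur < nbuckets:
                e = bhead[cur]
                if e < 0:
                    cur += 1
                    continue
                bhead[cur] = enext[e]
                u = enode[e]
                if visited[u] or dist[u] != cur:
                    continue
                visited[u] = True
                if u >= n and demand[u - n] > eps:
                    t_best = u
                    break
                if u < n:
                    pu = pot[u]
                    for j in range(m):
                        x = n + j
                        if visited[x]:
                            continue
                        nd = cur + Ci[u, j] + pu - pot[x]
                        if nd < dist[x]:
                            if nd >= nbuckets or ne >= cap:
                                return flow, pot.astype(np.float64), -1.0
                            dist[x] = nd
                            parent[x] = u
                            enode[ne] = x
                            enext[ne] = bhead[nd]
                            bhead[nd] = ne
                            ne += 1
                else:
                    j = u - n
                    pu = pot[u]
                    for i in range(n):
                        if visited[i] or flow[i, j] <= eps:
                            continue
                        nd = cur - Ci[i, j] + pu - pot[i]
                        if nd < dist[i]:
                            if nd >= nbuckets or ne >= cap:
                                return flow, pot.astype(np.float64), -1.0
                            dist[i] = nd
                            parent[i] = u
                            enode[ne] = i
                            enext[ne] = bhead[nd]
                            bhead[nd] = ne
                            ne += 1
            if t_best < 0:
                return flow, pot.astype(np.float64), -2.0
            dt = dist[t_best]
            for x in range(N):
                if dist[x] < dt:
                    pot[x] += dist[x]
                else:
                    pot[x] += dt
            delta = demand[t_best - n]
            x = t_best
            s = -1
            while True:
                p = parent[x]
                if p < 0:
                    s = x
                    break
                if x < n and flow[x, p - n] < delta:
                    delta = flow[x, p - n]
                x = p
            if supply[s] < delta:
                delta = supply[s]
            x = t_best
            while True:
                p = parent[x]
                if p < 0:
                    break
                if x >= n:
                    flow[p, x - n] += delta
                else:
                    flow[x, p - n] -= delta
                x = p
            supply[s] -= delta
            demand[t_best - n] -= delta
            total -= delta
        return flow, pot.astype(np.float64), 0.0

    @njit(cache=True)
    def _ssp_float(a, b, C):
        """SSP with scan-min Dijkstra; arbitrary non-negative float costs."""
        n = a.shape[0]
        m = b.shape[0]
        N = n + m
        flow = np.zeros((n, m))
        pot = np.zeros(N)
        supply = a.copy()
        demand = b.copy()
        total = supply.sum()
        eps = 1e-12 * max(1.0, total)
        dist = np.empty(N)
        visited = np.empty(N, numba.boolean)
        parent = np.empty(N, np.int64)
        guard = 0
        maxit = 16 * N * N + 1000
        while total > eps:
            guard += 1
            if guard > maxit:
                return flow, pot, -3.0
            for x in range(N):
                dist[x] = _INF
                visited[x] = False
                parent[x] = -1
            for i in range(n):
                if supply[i] > eps:
                    dist[i] = 0.0
            t_best = -1
            while True:
                u = -1
                du = _INF
                for x in range(N):
                    if not visited[x] and dist[x] < du:
                        du = dist[x]
                        u = x
                if u < 0:
                    break
                visited[u] = True
                if u >= n and demand[u - n] > eps:
                    t_best = u
                    break
                if u < n:
                    pu = pot[u]
                    for j in range(m):
                        x = n + j
                        if visited[x]:
                            continue
                        nd = du + C[u, j] + pu - pot[x]
                        if nd < dist[x] - 1e-15:
                            dist[x] = nd
                            parent[x] = u
                else:
                    j = u - n
                    pu = pot[u]
                    for i in range(n):
                        if visited[i] or flow[i, j] <= eps:
                            continue
                        nd = du - C[i, j] + pu - pot[i]
                        if nd < dist[i] - 1e-15:
                            dist[i] = nd
                            parent[i] = u
            if t_best < 0:
                return flow, pot, -2.0
            dt = dist[t_best]
            for x in range(N):
                if dist[x] < dt:
                    pot[x] += dist[x]
                else:
                    pot[x] += dt
            delta = demand[t_best - n]
            x = t_best
            s = -1
            while True:
                p = parent[x]
                if p < 0:
                    s = x
                    break
                if x < n and flow[x, p - n] < delta:
                    delta = flow[x, p - n]
                x = p
            if supply[s] < delta:
                delta = supply[s]
            x = t_best
            while True:
                p = parent[x]
                if p < 0:
                    break
                if x >= n:
                    flow[p, x - n] += delta
                else:
                    flow[x, p - n] -= delta
                x = p
            supply[s] -= delta
            demand[t_best - n] -= delta
            total -= delta
        return flow, pot, 0.0


if _HAVE_NUMBA:

    @njit(cache=True)
    def _greedy_transport_plan(a, b, C):
        """Feasible greedy plan: a valid upper bound on W1.

        Matrix-minimum rule: cells are served in order of increasing cost,
        each shipping as much mass as supply and demand allow.  Returns
        (cost, rows, cols, amounts, n_entries); every shipment saturates a
        row or a column, so at most n+m entries are produced.
        """
        n = a.shape[0]
        m = b.shape[0]
        supply = a.copy()
        demand = b.copy()
        order = np.argsort(C.ravel())
        total = 0.0
        left = supply.sum()
        cap = n + m + 2
        rows = np.empty(cap, np.int64)
        cols = np.empty(cap, np.int64)
        amts = np.empty(cap)
        cnt = 0
        for t in range(order.shape[0]):
            if left <= 1e-15 or cnt >= cap:
                break
            cell = order[t]
            k = cell // m
            l = cell - k * m
            if supply[k] > 1e-15 and demand[l] > 1e-15:
                amt = supply[k] if supply[k] < demand[l] else demand[l]
                total += amt * C[k, l]
                rows[cnt] = k
                cols[cnt] = l
                amts[cnt] = amt
                cnt += 1
                supply[k] -= amt
                demand[l] -= amt
                left -= amt
        return total, rows, cols, amts, cnt


def greedy_transport_bound(a: np.ndarray, b: np.ndarray, C: np.ndarray):
    """Upper bound on W1 from a feasible greedy plan.

    Returns (cost, rows, cols, amounts) with the plan's non-zero entries.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    C = np.ascontiguousarray(C, dtype=np.float64)
    if _HAVE_NUMBA:
        total, rows, cols, amts, cnt = _greedy_transport_plan(a, b, C)
        return float(total), rows[:cnt], cols[:cnt], amts[:cnt]
    plan, cost = solve_transport(a, b, C)  # pragma: no cover
    rows, cols = np.nonzero(plan)  # pragma: no cover
    return cost, rows, cols, plan[rows, cols]  # pragma: no cover


def linprog_transport(a: np.ndarray, b: np.ndarray, C: np.ndarray):
    """Solve the transportation LP with scipy's HiGHS backend.

    Slow but dependable; used as fallback and as an independent reference.
    Returns (plan, objective).
    """
    from scipy.optimize import linprog
    from scipy.sparse import eye, kron, vstack

    n, m = len(a), len(b)
    A_eq = vstack(
        [kron(eye(n), np.ones((1, m))), kron(np.ones((1, n)), eye(m))]
    ).tocsr()
    b_eq = np.concatenate([a, b])
    res = linprog(np.asarray(C, dtype=float).ravel(), A_eq=A_eq, b_eq=b_eq, method="highs")
    if not res.success:  # pragma: no cover - balanced problems are feasible
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return res.x.reshape(n, m), float(res.fun)


def _certified(a, b, C, flow, pot) -> bool:
    """Primal feasibility + LP duality certificate for an SSP solution."""
    n, m = len(a), len(b)
    if np.abs(flow.sum(axis=1) - a).max() > _FEAS_TOL:
        return False
    if np.abs(flow.sum(axis=0) - b).max() > _FEAS_TOL:
        return False
    if flow.min() < -_FEAS_TOL:
        return False
    alpha = -pot[:n]
    beta = pot[n:]
    # dual feasibility: alpha_k + beta_l <= d(k,l)
    if (alpha[:, None] + beta[None, :] - C).max() > _FEAS_TOL:
        return False
    primal = float((flow * C).sum())
    dual = float(a @ alpha + b @ beta)
    return abs(primal - dual) <= _FEAS_TOL * max(1.0, abs(primal))


def solve_transport(a: np.ndarray, b: np.ndarray, C: np.ndarray):
    """Exact optimal transport plan between discrete measures.

    Parameters
    ----------
    a, b : 1-D arrays of non-negative masses with equal sums (the marginals).
    C : cost matrix of shape (len(a), len(b)); entries must be non-negative
        and finite.

    Returns
    -------
    (plan, cost) with ``plan.sum(axis=1) == a`` and ``plan.sum(axis=0) == b``
    and ``cost`` the exact LP optimum.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    C = np.ascontiguousarray(C, dtype=np.float64)
    n, m = len(a), len(b)
    if C.shape != (n, m):
        raise ValueError(f"cost matrix shape {C.shape} != ({n}, {m})")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost matrix contains non-finite entries")
    if C.min() < 0:
        raise ValueError("cost matrix contains negative entries")
    if abs(a.sum() - b.sum()) > _FEAS_TOL:
        raise ValueError("marginals are not balanced")
    # trivial shapes: the plan is the outer product of the marginals
    if n == 1 or m == 1:
        plan = np.outer(a, b) / a.sum()
        return plan, float((plan * C).sum())
    if _HAVE_NUMBA:
        is_int = float(C.max()) <= 2**20 and np.all(C == np.floor(C))
        if is_int:
            Ci = C.astype(np.int64)
            nbuckets = max(64, int(4 * C.max()) + 16)
            while nbuckets <= 1 << 16:
                flow, pot, status = _ssp_int(a, b, Ci, nbuckets)
                if status == 0.0:
                    if _certified(a, b, C, flow, pot):
                        return flow, float((flow * C).sum())
                    break
                if status != -1.0:
                    break
                nbuckets *= 16
        else:
            flow, pot, status = _ssp_float(a, b, C)
            if status == 0.0 and _certified(a, b, C, flow, pot):
                return flow, float((flow * C).sum())
    return linprog_transport(a, b, C)
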