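"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive — queue BFS, triple enumeration,
exhaustive shortest-path enumeration, textbook IRLS — and shares no code
with the package implementation it checks.
"""

from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u, v] and not np.isfinite(dist[s, v]):
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
    return dist


def oracle_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        tri = sum(adj[a, b] for ai, a in enumerate(nb) for b in nb[ai + 1:])
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def oracle_global(adj: np.ndarray) -> dict:
    n = adj.shape[0]
    dist = bfs_distances(adj)
    finite = []
    eff_sum = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.isfinite(dist[i, j]):
                finite.append(dist[i, j])
                eff_sum += 1.0 / dist[i, j]
    lp = float(np.mean(finite)) if finite else 0.0
    eg = eff_sum / (n * (n - 1))
    neloc = oracle_nodal_local_efficiency(adj)
    return dict(
        Cp=float(oracle_clustering(adj).mean()),
        Lp=lp,
        Eg=eg,
        Eloc=float(neloc.mean()),
    )


def _subgraph_global_eff(adj: np.ndarray, nodes: list) -> float:
    k = len(nodes)
    if k < 2:
        return 0.0
    sub = adj[np.ix_(nodes, nodes)]
    dist = bfs_distances(sub)
    s = 0.0
    for i in range(k):
        for j in range(k):
            if i != j and np.isfinite(dist[i, j]):
                s += 1.0 / dist[i, j]
    return s / (k * (k - 1))


def oracle_nodal_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    return np.array(
        [_subgraph_global_eff(adj, [j for j in range(n) if adj[i, j]]) for i in range(n)]
    )


def oracle_nodal_global_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = bfs_distances(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / dist[i, j] for j in range(n) if j != i and np.isfinite(dist[i, j])
        ) / (n - 1)
    return out


def _all_shortest_paths(adj: np.ndarray, dist: np.ndarray, s: int, t: int) -> list:
    """Every shortest s-t path, found by depth-first extension along dist."""
    if not np.isfinite(dist[s, t]) or s == t:
        return []
    n = adj.shape[0]
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if adj[u, v] and dist[v, t] == dist[u, t] - 1:
                extend(path + [v])

    extend([s])
    return paths


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness: each unordered pair counted once."""
    n = adj.shape[0]
    dist = bfs_distances(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def irls_logistic(X: np.ndarray, y: np.ndarray, ridge: float, n_iter: int = 200) -> np.ndarray:
    """Ridge-penalized logistic ML by textbook IRLS; returns [intercept, slopes]."""
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = ridge * np.eye(p + 1)
    pen[0, 0] = 0.0
    for _ in range(n_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = design.T @ (y - mu) - pen @ beta
        hess = (design.T * w) @ design + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive pair counting (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the definition: p * m / rank, monotone."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return np.minimum(adj, 1.0)
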