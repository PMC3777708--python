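"""Independent brute-force oracles for graph quantities.

Everything here is deliberately naive (exhaustive enumeration, Floyd-
Warshall, explicit geodesic counting) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if adj[nbrs[a], nbrs[b]]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def oracle_distances(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall hop distances (inf where unreachable)."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj.astype(bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_cpl(adj: np.ndarray) -> float:
    d = oracle_distances(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(vals))


def oracle_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by explicit enumeration of all geodesics."""
    n = adj.shape[0]
    d = oracle_distances(adj)
    # count geodesics via DP on the shortest-path DAG
    sigma = np.zeros((n, n))
    for s in range(n):
        order = sorted(range(n), key=lambda v: d[s, v])
        sigma[s, s] = 1.0
        for v in order:
            if v == s or np.isinf(d[s, v]):
                continue
            sigma[s, v] = sum(
                sigma[s, u] for u in range(n) if adj[u, v] and d[s, u] + 1 == d[s, v]
            )
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if np.isinf(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t) or np.isinf(d[s, v]) or np.isinf(d[v, t]):
                    continue
                if d[s, v] + d[v, t] == d[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def oracle_participation(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for m in np.unique(labels):
            k_im = sum(adj[i, j] for j in range(n) if labels[j] == m)
            acc += (k_im / k) ** 2
        out[i] = 1.0 - acc
    return out


def oracle_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    m2 = adj.sum()  # 2m
    deg = adj.sum(axis=1)
    q = 0.0
    for s in np.unique(labels):
        idx = labels == s
        q += adj[np.ix_(idx, idx)].sum() / m2 - (deg[idx].sum() / m2) ** 2
    return float(q)


def oracle_best_partition(adj: np.ndarray) -> tuple[float, tuple]:
    """Exhaustive search over all set partitions (feasible for n <= 8)."""
    n = adj.shape[0]
    best_q, best = -np.inf, None

    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    for part in partitions(list(range(n))):
        labels = np.zeros(n, dtype=int)
        for m, block in enumerate(part):
            labels[block] = m
        q = oracle_modularity(adj, labels)
        if q > best_q:
            best_q, best = q, tuple(tuple(b) for b in part)
    return best_q, best


def oracle_bh(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * (np.arange(1, m + 1)) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    flags = np.zeros(m, dtype=bool)
    if below.size:
        flags[order[: below[-1] + 1]] = True
    return flags


def random_connected_graph(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random connected simple graph on n nodes (rejection sampling)."""
    while True:
        p = rng.uniform(0.3, 0.8)
        adj = rng.random((n, n)) < p
        adj = np.triu(adj, 1)
        adj = (adj | adj.T).astype(int)
        d = oracle_distances(adj.astype(float))
        if not np.isinf(d).any():
            return adj


def critical_r_bruteforce(n_obs: int, alpha: float, tails: str) -> float:
    """Numeric inversion of the t CDF over a fine r grid."""
    import scipy.stats

    df = n_obs - 2
    a = alpha if tails == "one" else alpha / 2
    rs = np.linspace(1e-6, 0.999999, 2_000_000)
    t = rs * np.sqrt(df / (1 - rs**2))
    pv = scipy.stats.t.sf(t, df)
    idx = np.argmax(pv < a)
    return float(rs[idx])
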