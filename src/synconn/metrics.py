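"""Sparsity thresholding and binary-graph metrics.

Weighted connectivity matrices are thresholded to a target *sparsity* (the
fraction of possible node pairs kept, taking the strongest positive weights
and ignoring negative ones), binarized, and characterized by six global
metrics: clustering coefficient (CC), characteristic path length (CPL),
their ratios to degree-preserving random-network averages, their ratio
small-worldness, and Louvain modularity Q.

Naming warning
--------------
Following the convention of the analyses this package reproduces, ``lambda``
denotes the *normalized clustering coefficient* (CC / null CC) and ``gamma``
the *normalized characteristic path length* (CPL / null CPL). This is the
REVERSE of the common small-world literature usage, where gamma is the
clustering ratio. Small-worldness = lambda / gamma either way.

Null networks are degree-preserving connected rewirings of the observed
graph (random double edge swaps constrained to keep the graph connected).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.stats

from ._seeds import child_int_seed, igraph_rng
from .community import Partition, mean_louvain_q
from .exceptions import DataError, DisconnectedGraphError

__all__ = [
    "BinaryGraph",
    "GlobalMetricSet",
    "MetricCurve",
    "NodalMetricSet",
    "METRIC_NAMES",
    "threshold_to_sparsity",
    "count_components",
    "clustering_coefficient",
    "characteristic_path_length",
    "betweenness_centrality",
    "participation_coefficient",
    "rewire_preserving_degree",
    "normalized_metrics",
    "metric_curve",
    "nodal_metrics",
    "critical_correlation",
    "default_functional_grid",
    "default_structural_grid",
]

METRIC_NAMES = ("cc", "cpl", "lambda", "gamma", "small_worldness", "q")


def default_functional_grid() -> np.ndarray:
    """15% to 32% sparsity in 1% increments (18 levels)."""
    return np.round(np.arange(0.15, 0.3201, 0.01), 4)


def default_structural_grid() -> np.ndarray:
    """5% to 8.5% sparsity in 0.5% increments (8 levels)."""
    return np.round(np.arange(0.05, 0.08501, 0.005), 4)


@dataclass(frozen=True)
class BinaryGraph:
    """Symmetric boolean adjacency with zero diagonal at a known sparsity."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise DataError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise DataError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise DataError("adjacency must have an empty diagonal (no self-loops)")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def to_igraph(self) -> igraph.Graph:
        iu = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu]
        edges = list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
        return igraph.Graph(n=self.n_nodes, edges=edges)

    @classmethod
    def from_igraph(cls, g: igraph.Graph, sparsity: float) -> "BinaryGraph":
        n = g.vcount()
        adj = np.zeros((n, n), dtype=bool)
        e = np.asarray(g.get_edgelist(), dtype=np.int64)
        if e.size:
            adj[e[:, 0], e[:, 1]] = True
            adj[e[:, 1], e[:, 0]] = True
        return cls(adjacency=adj, sparsity=sparsity)


@dataclass(frozen=True)
class GlobalMetricSet:
    """The six global metrics of one binary graph (see module docstring)."""

    cc: float
    cpl: float
    lambda_: float
    gamma: float
    small_worldness: float
    q: float

    def to_dict(self) -> dict:
        return {
            "cc": self.cc,
            "cpl": self.cpl,
            "lambda": self.lambda_,
            "gamma": self.gamma,
            "small_worldness": self.small_worldness,
            "q": self.q,
        }


@dataclass(frozen=True)
class MetricCurve:
    """Global metrics across a sparsity grid, with two summaries.

    ``summary()`` is the arithmetic mean over levels; ``summary_integrated()``
    is the trapezoidal integral over the grid normalized by the grid span,
    so a constant curve integrates to its constant value.
    """

    grid: np.ndarray
    levels: tuple[GlobalMetricSet, ...]

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or len(grid) != len(self.levels):
            raise DataError("grid and per-level metrics must align")
        if len(grid) > 1 and not np.all(np.diff(grid) > 0):
            raise DataError("sparsity grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "levels", tuple(self.levels))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [m.to_dict() for m in self.levels]
        return pd.DataFrame(rows, index=pd.Index(self.grid, name="sparsity"))

    def summary(self) -> dict:
        return self.to_dataframe().mean(axis=0).to_dict()

    def summary_integrated(self) -> dict:
        df = self.to_dataframe()
        if len(self.grid) == 1:
            return df.iloc[0].to_dict()
        span = self.grid[-1] - self.grid[0]
        return {
            c: float(np.trapezoid(df[c].to_numpy(), self.grid) / span) for c in df.columns
        }


@dataclass(frozen=True)
class NodalMetricSet:
    """Per-node clustering, betweenness and participation, grid-averaged."""

    clustering: np.ndarray
    betweenness: np.ndarray
    participation: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clustering": self.clustering,
                "betweenness": self.betweenness,
                "participation": self.participation,
            },
            index=pd.RangeIndex(len(self.clustering), name="node_id"),
        )


def _edge_quota(n_nodes: int, sparsity: float) -> int:
    # round-half-up of sparsity * number of possible edges
    m = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(sparsity * m + 0.5))


def threshold_to_sparsity(weights: np.ndarray, sparsity: float) -> BinaryGraph:
    """Keep the strongest positive weights to reach an exact edge quota.

    Exactly ``round(sparsity * N(N-1)/2)`` edges are kept: the largest
    strictly positive off-diagonal weights. Negative and zero weights never
    become edges. Ties at the cutoff are broken deterministically by
    (weight descending, then row, then column index).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DataError("weight matrix must be square")
    if not (0 < sparsity <= 1):
        raise DataError("sparsity must be in (0, 1]")
    n = w.shape[0]
    k = _edge_quota(n, sparsity)
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    pos = vals > 0
    n_pos = int(pos.sum())
    if k > n_pos:
        m = n * (n - 1) // 2
        raise DataError(
            f"sparsity {sparsity:g} needs {k} edges but only {n_pos} positive weights "
            f"exist (maximum achievable sparsity {n_pos / m:.4f})"
        )
    adj = np.zeros((n, n), dtype=bool)
    if k > 0:
        ip, jp, vp = iu[pos], ju[pos], vals[pos]
        order = np.lexsort((jp, ip, -vp))[:k]
        adj[ip[order], jp[order]] = True
        adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=float(sparsity))


def count_components(graph: BinaryGraph) -> int:
    """Number of connected components (isolated nodes count singly)."""
    n, _ = csgraph.connected_components(sp.csr_matrix(graph.adjacency), directed=False)
    return int(n)


def is_connected(graph: BinaryGraph) -> bool:
    return count_components(graph) == 1


def clustering_coefficient(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node binary clustering coefficients and their mean.

    Node i with degree k >= 2 scores 2 t_i / (k (k - 1)) where t_i counts
    triangles through i; nodes with degree < 2 score 0 and are included in
    the mean.
    """
    g = graph.to_igraph()
    vals = np.asarray(g.transitivity_local_undirected(mode="zero"), dtype=float)
    return vals, float(vals.mean())


def characteristic_path_length(graph: BinaryGraph) -> float:
    """Mean breadth-first shortest-path length over all unordered node pairs."""
    if graph.n_nodes < 2:
        raise DataError("need at least 2 nodes for a path length")
    d = csgraph.shortest_path(sp.csr_matrix(graph.adjacency), method="D", unweighted=True)
    iu = np.triu_indices(graph.n_nodes, k=1)
    vals = d[iu]
    if np.isinf(vals).any():
        raise DisconnectedGraphError("graph is disconnected: characteristic path length undefined")
    return float(vals.mean())


def betweenness_centrality(graph: BinaryGraph) -> np.ndarray:
    """Unnormalized shortest-path betweenness (each unordered pair counted once)."""
    g = graph.to_igraph()
    return np.asarray(g.betweenness(directed=False), dtype=float)


def participation_coefficient(graph: BinaryGraph, partition: Partition) -> np.ndarray:
    """PC_i = 1 - sum_s (k_is / k_i)^2 for a reference module partition.

    Nodes with degree 0 score 0 by convention.
    """
    if partition.n_nodes != graph.n_nodes:
        raise DataError("partition does not cover the graph's node set")
    adj = graph.adjacency.astype(float)
    onehot = np.eye(partition.n_modules)[partition.labels]  # N x M
    k_is = adj @ onehot
    k = adj.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, k_is / np.maximum(k[:, None], 1), 0.0)
    pc = 1.0 - (frac**2).sum(axis=1)
    pc[k == 0] = 0.0
    return pc


def rewire_preserving_degree(
    graph: BinaryGraph, seed: int = 0, n_swaps_per_edge: float = 10.0
) -> BinaryGraph:
    """Degree-preserving connected rewiring by random double edge swaps.

    Attempts ``n_swaps_per_edge * E`` double edge swaps. Swaps are applied
    in batches; after each batch connectedness is checked and a batch that
    disconnected the graph is rolled back (progressively smaller batches are
    used if rollbacks recur). The result always has the exact degree
    sequence of the input and is connected. Seed-reproducible.

    Graphs that admit no degree-preserving alternative (e.g. a triangle or a
    complete graph) come back with the identical edge set, with a warning.
    """
    if not is_connected(graph):
        raise DisconnectedGraphError("rewiring null model requires a connected graph")
    g = graph.to_igraph()
    total = max(int(round(n_swaps_per_edge * g.ecount())), 1)
    igraph_rng(seed)
    # Fast path: swap everything at once, accept if still connected.
    trial = g.copy()
    trial.rewire(n=total)
    if trial.is_connected():
        out = trial
    else:
        # Windowed fallback: batch, check, roll back on disconnection.
        cur = g.copy()
        done = 0
        batch = max(total // 10, 1)
        failures = 0
        while done < total and failures < 50:
            trial = cur.copy()
            step = min(batch, total - done)
            trial.rewire(n=step)
            if trial.is_connected():
                cur = trial
                done += step
            else:
                failures += 1
                batch = max(batch // 2, 1)
        out = cur
    result = BinaryGraph.from_igraph(out, sparsity=graph.sparsity)
    if np.array_equal(result.adjacency, graph.adjacency):
        warnings.warn(
            "rewiring left the edge set unchanged (no degree-preserving "
            "alternative was reachable); returning an identical copy",
            stacklevel=2,
        )
    return result


def normalized_metrics(
    graph: BinaryGraph,
    n_nulls: int = 100,
    seed: int = 0,
    n_swaps_per_edge: float = 10.0,
    cc: float | None = None,
    cpl: float | None = None,
) -> dict:
    """lambda, gamma and small-worldness against a rewired null ensemble.

    lambda = CC / mean(null CC), gamma = CPL / mean(null CPL),
    small_worldness = lambda / gamma. ``cc``/``cpl`` may be passed in if
    already computed for the observed graph.
    """
    if n_nulls < 1:
        raise DataError("n_nulls must be >= 1")
    if cc is None:
        cc = clustering_coefficient(graph)[1]
    if cpl is None:
        cpl = characteristic_path_length(graph)
    null_cc = np.empty(n_nulls)
    null_cpl = np.empty(n_nulls)
    for i in range(n_nulls):
        null = rewire_preserving_degree(
            graph, seed=child_int_seed(seed, f"null-{i}"), n_swaps_per_edge=n_swaps_per_edge
        )
        null_cc[i] = clustering_coefficient(null)[1]
        null_cpl[i] = characteristic_path_length(null)
    mean_cc = null_cc.mean()
    mean_cpl = null_cpl.mean()
    if mean_cc == 0 or mean_cpl == 0:
        raise DataError("null ensemble has zero mean CC or CPL; normalization undefined")
    lam = cc / mean_cc
    gam = cpl / mean_cpl
    return {"lambda": float(lam), "gamma": float(gam), "small_worldness": float(lam / gam)}


def metric_curve(
    weights: np.ndarray,
    grid: np.ndarray | None = None,
    n_nulls: int = 100,
    n_louvain: int = 100,
    seed: int = 0,
    n_swaps_per_edge: float = 10.0,
) -> MetricCurve:
    """The six global metrics at every sparsity level of a grid.

    Every level must give a connected graph (thresholded edge sets are
    nested, so in practice connectivity at the smallest sparsity implies it
    everywhere); otherwise an error lists the failing levels.
    """
    grid = default_functional_grid() if grid is None else np.asarray(grid, dtype=float)
    graphs = [threshold_to_sparsity(weights, s) for s in grid]
    bad = [float(s) for s, g in zip(grid, graphs) if not is_connected(g)]
    if bad:
        raise DisconnectedGraphError(
            f"graph disconnected at sparsity level(s) {bad}; restrict the grid to the connected range",
            failing_levels=bad,
        )
    levels = []
    for s, g in zip(grid, graphs):
        _, cc = clustering_coefficient(g)
        cpl = characteristic_path_length(g)
        norm = normalized_metrics(
            g,
            n_nulls=n_nulls,
            seed=child_int_seed(seed, f"nulls-s{s}"),
            n_swaps_per_edge=n_swaps_per_edge,
            cc=cc,
            cpl=cpl,
        )
        q = mean_louvain_q(
            g.adjacency.astype(float), n_iter=n_louvain, seed=child_int_seed(seed, f"q-s{s}")
        )
        levels.append(
            GlobalMetricSet(
                cc=cc,
                cpl=cpl,
                lambda_=norm["lambda"],
                gamma=norm["gamma"],
                small_worldness=norm["small_worldness"],
                q=q,
            )
        )
    return MetricCurve(grid=grid, levels=tuple(levels))


def nodal_metrics(
    weights: np.ndarray,
    partition: Partition,
    grid: np.ndarray | None = None,
) -> NodalMetricSet:
    """Per-node clustering, betweenness and participation averaged over a grid.

    Participation is computed against a reference partition (typically the
    group-representative functional partition), the same one for every
    subject.
    """
    grid = default_functional_grid() if grid is None else np.asarray(grid, dtype=float)
    n = np.asarray(weights).shape[0]
    acc = {k: np.zeros(n) for k in ("clustering", "betweenness", "participation")}
    for s in grid:
        g = threshold_to_sparsity(weights, s)
        acc["clustering"] += clustering_coefficient(g)[0]
        acc["betweenness"] += betweenness_centrality(g)
        acc["participation"] += participation_coefficient(g, partition)
    m = float(len(grid))
    return NodalMetricSet(
        clustering=acc["clustering"] / m,
        betweenness=acc["betweenness"] / m,
        participation=acc["participation"] / m,
    )


def critical_correlation(n_obs: int, alpha: float = 0.05, tails: str = "one") -> float:
    """Smallest correlation reaching significance for a given sample size.

    Inverts t = r sqrt((n-2) / (1-r^2)) at the Student-t critical value with
    n-2 degrees of freedom. ``tails`` is "one" or "two".
    """
    if n_obs < 4:
        raise DataError("need n_obs >= 4")
    if not (0 < alpha < 1):
        raise DataError("alpha must be in (0, 1)")
    if tails not in ("one", "two"):
        raise DataError('tails must be "one" or "two"')
    df = n_obs - 2
    tail_alpha = alpha if tails == "one" else alpha / 2
    t_crit = scipy.stats.t.ppf(1 - tail_alpha, df)
    return float(t_crit / math.sqrt(df + t_crit**2))
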