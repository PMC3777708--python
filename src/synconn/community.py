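"""Community detection and partition comparison.

Louvain community detection on non-negative weighted (or binary) adjacency
matrices, Newman modularity Q, selection of a representative partition over
repeated stochastic runs, and normalized mutual information (NMI) between
partitions.

The Louvain engine is igraph's ``community_multilevel`` (the classical greedy
two-phase local-move + aggregation algorithm, resolution fixed at 1); Q and
NMI are computed directly from their definitions so they can be audited
against independent implementations.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import igraph
import numpy as np

from ._seeds import child_int_seed, igraph_rng
from .exceptions import DataError

__all__ = [
    "Partition",
    "ModularityResult",
    "positive_part",
    "louvain_partition",
    "modularity_q",
    "representative_partition",
    "mean_louvain_q",
    "nmi",
]


@dataclass(frozen=True)
class Partition:
    """A hard assignment of every node to exactly one module.

    Module ids are relabeled to be contiguous from 0 in order of first
    appearance, so partitions that differ only by label permutation compare
    equal in NMI but not necessarily in raw labels.
    """

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size == 0:
            raise DataError("partition labels must be a non-empty 1-D sequence")
        # contiguous relabeling in order of first appearance
        _, first_index = np.unique(labels, return_index=True)
        order = labels[np.sort(first_index)]
        mapping = {lab: i for i, lab in enumerate(order)}
        relabeled = np.array([mapping[v] for v in labels], dtype=np.int64)
        object.__setattr__(self, "labels", relabeled)

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and np.array_equal(self.labels, other.labels)

    def __hash__(self):
        return hash(self.labels.tobytes())


@dataclass(frozen=True)
class ModularityResult:
    """Outcome of a (possibly repeated) Louvain run."""

    partition: Partition
    q: float
    n_runs: int = 1
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)


def positive_part(weights: np.ndarray) -> np.ndarray:
    """Zero out negative weights (functional matrices enter Louvain this way)."""
    w = np.asarray(weights, dtype=float).copy()
    w[w < 0] = 0.0
    return w


def _as_igraph(weights: np.ndarray) -> tuple[igraph.Graph, np.ndarray | None]:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DataError("adjacency must be a square matrix")
    if np.any(w < 0):
        raise DataError("Louvain operates on non-negative weights; remove negative edges first")
    iu = np.triu_indices(w.shape[0], k=1)
    vals = w[iu]
    nz = vals > 0
    if not np.any(nz):
        raise DataError("matrix has no positive edge weight; community detection undefined")
    edges = list(zip(iu[0][nz].tolist(), iu[1][nz].tolist()))
    g = igraph.Graph(n=w.shape[0], edges=edges)
    wts = vals[nz]
    binary = np.allclose(wts, 1.0)
    return g, (None if binary else wts)


def louvain_partition(weights: np.ndarray, seed: int = 0) -> ModularityResult:
    """One Louvain run on a non-negative symmetric weight (or 0/1) matrix.

    Node-visit order is stochastic; the run is reproducible given ``seed``.
    """
    g, wts = _as_igraph(weights)
    igraph_rng(seed)
    clustering = g.community_multilevel(weights=wts)
    part = Partition(np.asarray(clustering.membership))
    q = modularity_q(weights, part)
    return ModularityResult(partition=part, q=q, n_runs=1, seed=seed)


def modularity_q(weights: np.ndarray, partition: Partition) -> float:
    """Newman modularity Q of a given partition.

    Q = sum_s [ W_s / W  -  (S_s / 2W)^2 ], where W is total edge weight,
    W_s the weight inside module s and S_s the total strength of module s.
    Works identically for binary adjacency (weights in {0, 1}).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DataError("adjacency must be a square matrix")
    if w.shape[0] != partition.n_nodes:
        raise DataError("partition size does not match matrix size")
    if np.any(w < 0):
        raise DataError("modularity is defined here for non-negative weights")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    two_w = w.sum()  # = 2W for a symmetric matrix
    if two_w == 0:
        raise DataError("empty graph: modularity undefined")
    labels = partition.labels
    strength = w.sum(axis=1)
    q = 0.0
    for s in range(partition.n_modules):
        idx = labels == s
        q += w[np.ix_(idx, idx)].sum() / two_w - (strength[idx].sum() / two_w) ** 2
    return float(q)


def mean_louvain_q(weights: np.ndarray, n_iter: int = 100, seed: int = 0) -> float:
    """Q averaged over repeated Louvain runs (module assignment is stochastic)."""
    if n_iter < 1:
        raise DataError("n_iter must be >= 1")
    qs = [louvain_partition(weights, seed=child_int_seed(seed, f"q-iter-{i}")).q for i in range(n_iter)]
    return float(np.mean(qs))


def representative_partition(
    weights: np.ndarray, n_runs: int = 100, seed: int = 0
) -> tuple[Partition, dict]:
    """Representative partition over repeated Louvain runs.

    Runs Louvain ``n_runs`` times with distinct sub-seeds, keeps the runs
    whose module count equals the modal count (ties broken toward the smaller
    count), and among those returns the partition with the highest mean NMI
    to the other retained runs (a deterministic stand-in for picking one
    modal-count run at random).

    Returns the partition and a diagnostics dict with the module-count
    histogram, modal count and its frequency, mean pairwise NMI among all
    runs, and the winning run's mean NMI.
    """
    if n_runs < 1:
        raise DataError("n_runs must be >= 1")
    runs = [louvain_partition(weights, seed=child_int_seed(seed, f"rep-run-{i}")) for i in range(n_runs)]
    counts = Counter(r.partition.n_modules for r in runs)
    top = max(counts.values())
    modal = min(k for k, v in counts.items() if v == top)
    kept = [r for r in runs if r.partition.n_modules == modal]
    if len(kept) == 1:
        best = kept[0]
        best_score = 1.0
    else:
        nmis = np.zeros((len(kept), len(kept)))
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                nmis[a, b] = nmis[b, a] = nmi(kept[a].partition, kept[b].partition)
        mean_to_others = nmis.sum(axis=1) / (len(kept) - 1)
        winner = int(np.argmax(mean_to_others))  # argmax: first (lowest sub-seed) wins ties
        best = kept[winner]
        best_score = float(mean_to_others[winner])
    all_nmi = np.nan
    if n_runs > 1:
        vals = [
            nmi(runs[a].partition, runs[b].partition)
            for a in range(n_runs)
            for b in range(a + 1, n_runs)
        ]
        all_nmi = float(np.mean(vals))
    diagnostics = {
        "module_count_histogram": dict(sorted(counts.items())),
        "modal_module_count": int(modal),
        "modal_frequency": top / n_runs,
        "mean_pairwise_nmi": all_nmi,
        "winner_mean_nmi": best_score,
        "winner_q": best.q,
    }
    return best.partition, diagnostics


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalized mutual information, 2 I(P1;P2) / (H(P1) + H(P2)).

    1 for identical partitions up to relabeling, 0 for independent ones.
    When either partition is the trivial single module its entropy is 0; if
    both entropies are 0 the partitions are identical and NMI is defined as
    1, otherwise the ratio's numerator I is 0 and NMI is 0.
    """
    if p1.n_nodes != p2.n_nodes:
        raise DataError("partitions are over different node sets")
    n = p1.n_nodes
    joint = np.zeros((p1.n_modules, p2.n_modules))
    np.add.at(joint, (p1.labels, p2.labels), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ha = -np.sum(pa * np.log(pa, where=pa > 0, out=np.zeros_like(pa)))
        hb = -np.sum(pb * np.log(pb, where=pb > 0, out=np.zeros_like(pb)))
        outer = np.outer(pa, pb)
        ratio = np.divide(joint, outer, where=joint > 0, out=np.ones_like(joint))
        mi = np.sum(joint * np.log(ratio, where=joint > 0, out=np.zeros_like(joint)))
    if ha + hb == 0:
        return 1.0
    val = 2.0 * mi / (ha + hb)
    return float(min(max(val, 0.0), 1.0))
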