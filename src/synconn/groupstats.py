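"""Edge-wise, nodal and global two-group statistics.

Two-sample Student t-tests (pooled variance by default, Welch by flag) at
every edge, node or global metric; Benjamini-Hochberg FDR control; the
within/between-module x positive/negative edge classification; counts and
strength/distance stratification of significant edges; and per-subject
structure-function correlations compared between groups.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .community import Partition
from .exceptions import DataError

__all__ = [
    "bh_fdr",
    "two_sample_t",
    "edgewise_group_test",
    "classify_edge_difference",
    "stratify_differences",
    "nodal_group_test",
    "global_metric_test",
    "structure_function_correlation",
]

EDGE_CLASSES = (
    "within_positive",
    "between_positive",
    "within_negative",
    "between_negative",
)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Vectorized two-sample t over axis 0; zero-variance columns give t=0, p=1.

    Returns (t, p, degenerate) where ``degenerate`` flags columns whose
    samples had no variance in either group (their test is uninformative).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("need at least 2 subjects per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return t, p, degenerate


def _upper_edges(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def edgewise_group_test(
    matrices_a,
    matrices_b,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
    group_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Two-sample t-test of edge weight per edge.

    ``matrices_*`` are per-subject symmetric matrices; ``edges`` restricts
    the test to given (i, j) index arrays (default: all upper-triangle
    pairs). Returns one row per edge with group means, t, p, pooled mean
    across all subjects, significance at ``alpha`` and the favored group.
    For edges with positive pooled mean the favored group is the one with
    the larger mean (stronger positive); for negative pooled mean it is the
    one with the more negative mean (stronger negative connectivity).
    """
    ma = [np.asarray(m, dtype=float) for m in matrices_a]
    mb = [np.asarray(m, dtype=float) for m in matrices_b]
    if not ma or not mb:
        raise DataError("both groups need subjects")
    n = ma[0].shape[0]
    if edges is None:
        edges = _upper_edges(n)
    ii, jj = np.asarray(edges[0]), np.asarray(edges[1])
    va = np.stack([m[ii, jj] for m in ma])
    vb = np.stack([m[ii, jj] for m in mb])
    t, p, degen = two_sample_t(va, vb, equal_var=equal_var)
    mean_a, mean_b = va.mean(axis=0), vb.mean(axis=0)
    pooled = np.concatenate([va, vb]).mean(axis=0)
    favored = np.where(
        pooled >= 0,
        np.where(mean_a >= mean_b, group_names[0], group_names[1]),
        np.where(mean_a <= mean_b, group_names[0], group_names[1]),
    )
    return pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            f"mean_{group_names[0]}": mean_a,
            f"mean_{group_names[1]}": mean_b,
            "mean_all": pooled,
            "t": t,
            "p": p,
            "significant": p < alpha,
            "degenerate": degen,
            "direction": favored,
        }
    )


def classify_edge_difference(
    results: pd.DataFrame, partition: Partition, coordinates: np.ndarray | None = None
) -> pd.DataFrame:
    """Attach the edge class and (optionally) inter-node distance.

    Class is within/between module (from the reference partition) crossed
    with positive/negative (sign of the pooled mean across all subjects;
    an exact zero counts as positive by convention). Every edge gets exactly
    one class.
    """
    df = results.copy()
    labels = partition.labels
    same = labels[df["i"].to_numpy()] == labels[df["j"].to_numpy()]
    negative = df["mean_all"].to_numpy() < 0
    df["edge_class"] = np.where(
        same,
        np.where(negative, "within_negative", "within_positive"),
        np.where(negative, "between_negative", "between_positive"),
    )
    if coordinates is not None:
        coords = np.asarray(coordinates, dtype=float)
        df["distance"] = np.linalg.norm(
            coords[df["i"].to_numpy()] - coords[df["j"].to_numpy()], axis=1
        )
    return df


def stratify_differences(
    classified: pd.DataFrame,
    by: str = "strength",
    group_names: tuple[str, str] = ("A", "B"),
) -> dict:
    """Counts and strength/distance comparison of significant edges by class.

    For each edge class, counts the significant edges favoring each group,
    their ratio, and compares the edge property (pooled mean strength or
    Euclidean distance) between the two favored sets with a two-sample
    t-test. A comparison with fewer than 2 edges on a side is skipped with a
    note.
    """
    if by == "strength":
        col = "mean_all"
    elif by == "distance":
        if "distance" not in classified.columns:
            raise DataError("distance stratification needs classified results with distances")
        col = "distance"
    else:
        raise DataError('stratify by "strength" or "distance"')
    sig = classified[classified["significant"] & ~classified["degenerate"]]
    out: dict = {"by": by, "classes": {}}
    for cls in EDGE_CLASSES:
        rows = sig[sig["edge_class"] == cls]
        set_a = rows[rows["direction"] == group_names[0]][col].to_numpy()
        set_b = rows[rows["direction"] == group_names[1]][col].to_numpy()
        entry = {
            f"n_{group_names[0]}": int(set_a.size),
            f"n_{group_names[1]}": int(set_b.size),
            "ratio": float(set_a.size / set_b.size) if set_b.size else np.inf if set_a.size else np.nan,
            f"mean_{group_names[0]}": float(set_a.mean()) if set_a.size else np.nan,
            f"mean_{group_names[1]}": float(set_b.mean()) if set_b.size else np.nan,
        }
        if set_a.size >= 2 and set_b.size >= 2:
            t, p, degen = two_sample_t(set_a[:, None], set_b[:, None])
            entry["t"] = float(t[0])
            entry["p"] = float(p[0])
        else:
            entry["note"] = "comparison skipped: too few edges in a category"
        out["classes"][cls] = entry
    return out


def nodal_group_test(
    table_a: pd.DataFrame | np.ndarray,
    table_b: pd.DataFrame | np.ndarray,
    q: float = 0.05,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-node two-sample tests with uncorrected and FDR-corrected flags.

    Inputs are subjects x nodes tables of one grid-averaged nodal metric.
    """
    a = np.asarray(getattr(table_a, "values", table_a), dtype=float)
    b = np.asarray(getattr(table_b, "values", table_b), dtype=float)
    t, p, degen = two_sample_t(a, b, equal_var=equal_var)
    flags = bh_fdr(p, q=q)
    return pd.DataFrame(
        {
            "node_id": np.arange(t.size),
            "mean_a": a.mean(axis=0),
            "mean_b": b.mean(axis=0),
            "t": t,
            "p": p,
            "significant_uncorrected": p < alpha,
            "significant_fdr": flags,
            "degenerate": degen,
        }
    )


def global_metric_test(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    q: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-metric two-sample tests, FDR-corrected across the metric family.

    Inputs are subjects x metrics tables (typically the six grid-averaged
    global metrics). Metrics constant across all subjects of both groups are
    skipped with a note and excluded from the FDR family.
    """
    cols = list(table_a.columns)
    if list(table_b.columns) != cols:
        raise DataError("both groups must provide the same metrics")
    a = table_a.to_numpy(dtype=float)
    b = table_b.to_numpy(dtype=float)
    t, p, degen = two_sample_t(a, b, equal_var=equal_var)
    tested = ~degen
    flags = np.zeros(len(cols), dtype=bool)
    if tested.any():
        flags[tested] = bh_fdr(p[tested], q=q)
    return pd.DataFrame(
        {
            "metric": cols,
            "mean_a": a.mean(axis=0),
            "sd_a": a.std(axis=0, ddof=1),
            "mean_b": b.mean(axis=0),
            "sd_b": b.std(axis=0, ddof=1),
            "t": t,
            "p": p,
            "significant_fdr": flags,
            "note": np.where(degen, "skipped: metric constant across subjects", ""),
        }
    )


def structure_function_correlation(
    functional,
    structural,
    mask: np.ndarray,
    groups=None,
    subset: str = "all",
    partition: Partition | None = None,
    custom_edges: tuple[np.ndarray, np.ndarray] | None = None,
    equal_var: bool = True,
) -> dict:
    """Per-subject correlation of fiber count with functional strength.

    For each subject, Pearson r between fiber counts and functional Fisher-z
    over the masked edge set (optionally restricted to within-module,
    between-module or custom edges), Fisher-z transformed (perfect |r| = 1
    is capped at 1 - 1e-6 with a warning), then compared between groups.

    Returns {"subjects": DataFrame, "group_test": DataFrame or None}.
    """
    functional = list(functional)
    structural = list(structural)
    if len(functional) != len(structural):
        raise DataError("functional and structural cohorts must align")
    mask = np.asarray(mask, dtype=bool)
    n = mask.shape[0]
    ii, jj = _upper_edges(n)
    keep = mask[ii, jj]
    if subset == "within" or subset == "between":
        if partition is None:
            raise DataError("module subsets need a reference partition")
        same = partition.labels[ii] == partition.labels[jj]
        keep = keep & (same if subset == "within" else ~same)
    elif subset == "custom":
        if custom_edges is None:
            raise DataError("custom subset needs custom_edges")
        sel = np.zeros((n, n), dtype=bool)
        sel[custom_edges[0], custom_edges[1]] = True
        sel |= sel.T
        keep = keep & sel[ii, jj]
    elif subset != "all":
        raise DataError('subset must be "all", "within", "between" or "custom"')
    if keep.sum() < 3:
        raise DataError(f"masked edge subset has {int(keep.sum())} edges; need >= 3")
    ei, ej = ii[keep], jj[keep]

    rows = []
    for s, (f, st) in enumerate(zip(functional, structural)):
        fw = getattr(f, "weights", f)
        fc = getattr(st, "fiber_count", st)
        x = np.asarray(fc, dtype=float)[ei, ej]
        y = np.asarray(fw, dtype=float)[ei, ej]
        if x.std() == 0 or y.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= 1.0 - 1e-12:
            warnings.warn(
                f"subject {s}: perfect structure-function correlation capped for the z transform",
                stacklevel=2,
            )
            r = math.copysign(1.0 - 1e-6, r)
        rows.append({"subject": s, "r": r, "z": float(np.arctanh(r)), "n_edges": int(keep.sum())})
    subjects = pd.DataFrame(rows)
    group_test = None
    if groups is not None:
        groups = np.asarray(groups)
        za = subjects.loc[groups == 0, "z"].to_numpy()[:, None]
        zb = subjects.loc[groups == 1, "z"].to_numpy()[:, None]
        t, p, _ = two_sample_t(za, zb, equal_var=equal_var)
        group_test = pd.DataFrame(
            {
                "mean_r_a": [float(np.tanh(za.mean()))],
                "mean_r_b": [float(np.tanh(zb.mean()))],
                "t": [float(t[0])],
                "p": [float(p[0])],
            }
        )
        subjects["group"] = groups
    return {"subjects": subjects, "group_test": group_test}
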