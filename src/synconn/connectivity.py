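"""Construction of functional and structural connectivity matrices.

Functional connectomes are Fisher z-transformed Pearson correlations between
node time series (z = arctanh r), stored as exactly symmetric matrices with
a zero diagonal. Structural connectomes count streamlines whose two
endpoints terminate inside the spheres of two different nodes, with per-edge
mean fractional anisotropy (FA) and mean diffusivity (MD) averaged over the
connecting streamlines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError

__all__ = [
    "FunctionalConnectome",
    "Streamline",
    "StructuralConnectome",
    "build_functional_matrix",
    "assign_streamline_endpoints",
    "build_structural_matrices",
    "apply_fiber_mask",
]


def _check_square_symmetric(mat: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mat)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataError(f"{name} must be square")
    if not np.array_equal(m, m.T):
        raise DataError(f"{name} must be exactly symmetric")
    return m


@dataclass(frozen=True)
class FunctionalConnectome:
    """Symmetric signed Fisher-z edge-weight matrix for one subject."""

    weights: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        w = _check_square_symmetric(self.weights, "functional weight matrix").astype(float)
        if np.any(np.diag(w) != 0):
            raise DataError("functional matrix diagonal must be zero by convention")
        if not np.all(np.isfinite(w)):
            raise DataError("functional matrix contains non-finite values")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class Streamline:
    """An ordered 3-D polyline in mm, optionally carrying FA/MD samples."""

    points: np.ndarray
    fa: np.ndarray | None = None
    md: np.ndarray | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise DataError("a streamline needs >= 2 points of 3 coordinates")
        object.__setattr__(self, "points", pts)
        for name in ("fa", "md"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    @property
    def length(self) -> float:
        """Polyline length in mm (sum of segment lengths)."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class StructuralConnectome:
    """Fiber-count, FA and MD matrices for one subject.

    ``fa_mean``/``md_mean`` are defined (non-NaN) only where ``fiber_count``
    is positive.
    """

    fiber_count: np.ndarray
    fa_mean: np.ndarray
    md_mean: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        fc = _check_square_symmetric(self.fiber_count, "fiber count matrix")
        if not np.issubdtype(fc.dtype, np.integer):
            if not np.allclose(fc, np.round(fc)):
                raise DataError("fiber counts must be integers")
            fc = np.round(fc).astype(np.int64)
        if np.any(fc < 0):
            raise DataError("fiber counts must be non-negative")
        fa = np.asarray(self.fa_mean, dtype=float)
        md = np.asarray(self.md_mean, dtype=float)
        for name, m in (("fa_mean", fa), ("md_mean", md)):
            if m.shape != fc.shape:
                raise DataError(f"{name} shape does not match fiber_count")
        defined = fc > 0
        if np.any((fa[defined] < 0) | (fa[defined] > 1)):
            raise DataError("FA must lie in [0, 1] where defined")
        if np.any(md[defined] <= 0):
            raise DataError("MD must be positive where defined")
        object.__setattr__(self, "fiber_count", fc)
        object.__setattr__(self, "fa_mean", fa)
        object.__setattr__(self, "md_mean", md)

    @property
    def n_nodes(self) -> int:
        return self.fiber_count.shape[0]


def build_functional_matrix(timeseries, subject_id: str = "") -> FunctionalConnectome:
    """Fisher-z correlation matrix from a T x N node time-series table.

    Every pair (i, j) gets z_ij = arctanh(Pearson r of columns i and j);
    the diagonal is stored as 0 by convention. Constant columns and perfect
    off-diagonal correlations are rejected as degenerate.
    """
    x = np.asarray(getattr(timeseries, "values", timeseries), dtype=float)
    if x.ndim != 2:
        raise DataError("time series must be a 2-D T x N table")
    t, n = x.shape
    if t < 3:
        raise DataError("need at least 3 time points to correlate")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DataError(f"zero-variance time series for node(s) {dead.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) >= 1.0 - 1e-12):
        i, j = np.unravel_index(int(np.argmax(np.abs(r))), r.shape)
        raise DataError(f"perfect correlation between nodes {i} and {j}: degenerate input")
    z = np.arctanh(r)
    return FunctionalConnectome(weights=z, subject_id=subject_id)


def assign_streamline_endpoints(
    streamline: Streamline,
    nodes,
    radius: float = 10.0,
    min_length: float = 5.0,
) -> tuple[int, int] | None:
    """Node pair whose spheres contain the streamline's two endpoints.

    Returns (i, j) with i != j iff the streamline is at least ``min_length``
    mm long and each endpoint lies within ``radius`` mm of a node center;
    an endpoint falling inside several overlapping spheres is assigned to
    the nearest center (ties to the lower node id). Otherwise None: too
    short, an endpoint outside every sphere, or both endpoints in the same
    node's sphere.
    """
    if radius <= 0:
        raise DataError("radius must be positive")
    if streamline.length < min_length:
        return None
    coords = np.asarray(getattr(nodes, "coordinates", nodes), dtype=float)
    ends = streamline.points[[0, -1]]
    pair = []
    for e in ends:
        d = np.linalg.norm(coords - e, axis=1)
        best = int(np.argmin(d))  # argmin takes the lowest index on ties
        if d[best] > radius:
            return None
        pair.append(best)
    i, j = pair
    if i == j:
        return None
    return (min(i, j), max(i, j))


def build_structural_matrices(
    streamlines,
    nodes,
    radius: float = 10.0,
    min_length: float = 5.0,
    subject_id: str = "",
) -> StructuralConnectome:
    """Count assigned streamlines per node pair and average their FA/MD.

    Edge FA (MD) is the mean over connecting streamlines of each
    streamline's mean FA (MD) sample. Pairs with no streamline carry NaN.
    """
    coords = np.asarray(getattr(nodes, "coordinates", nodes), dtype=float)
    n = coords.shape[0]
    count = np.zeros((n, n), dtype=np.int64)
    fa_sum = np.zeros((n, n))
    md_sum = np.zeros((n, n))
    fa_n = np.zeros((n, n), dtype=np.int64)
    md_n = np.zeros((n, n), dtype=np.int64)
    for s in streamlines:
        hit = assign_streamline_endpoints(s, coords, radius=radius, min_length=min_length)
        if hit is None:
            continue
        i, j = hit
        count[i, j] += 1
        if s.fa is not None:
            fa_sum[i, j] += float(np.mean(s.fa))
            fa_n[i, j] += 1
        if s.md is not None:
            md_sum[i, j] += float(np.mean(s.md))
            md_n[i, j] += 1
    count = count + count.T
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(fa_n > 0, fa_sum / np.maximum(fa_n, 1), np.nan)
        md = np.where(md_n > 0, md_sum / np.maximum(md_n, 1), np.nan)
    fa = np.where(np.isnan(fa), fa.T, fa)
    md = np.where(np.isnan(md), md.T, md)
    return StructuralConnectome(
        fiber_count=count, fa_mean=fa, md_mean=md, subject_id=subject_id
    )


def apply_fiber_mask(connectomes, threshold: float = 5.0) -> np.ndarray:
    """Edges whose cohort-average fiber count reaches the threshold.

    mask(i, j) is True iff the mean over subjects of fiber_count(i, j) is
    ``threshold`` or more ("5 or more" includes exactly 5). Emits a warning
    if no edge survives.
    """
    connectomes = list(connectomes)
    if not connectomes:
        raise DataError("need at least one subject to build a fiber mask")
    n = connectomes[0].n_nodes
    acc = np.zeros((n, n), dtype=float)
    for c in connectomes:
        if c.n_nodes != n:
            raise DataError("all structural connectomes must share one node set")
        acc += c.fiber_count
    mean = acc / len(connectomes)
    mask = mean >= threshold
    np.fill_diagonal(mask, False)
    if not mask.any():
        warnings.warn("fiber mask is empty: no edge averages enough fibers", stacklevel=2)
    return mask
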