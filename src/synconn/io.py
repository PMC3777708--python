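"""Reading and writing of the package's delimited-text formats.

Matrices, node tables, time series, phenotype tables and partitions are all
plain TSV; streamlines use a simple whitespace-delimited point-list format
(one point per line: x y z [fa md], blank line between streamlines).
Configuration files are YAML key-value mappings of CohortConfig /
PipelineConfig fields.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import NodeSet
from .community import Partition
from .connectivity import Streamline
from .exceptions import DataError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_node_table",
    "write_node_table",
    "read_timeseries",
    "write_timeseries",
    "read_phenotypes",
    "write_phenotypes",
    "read_partition",
    "write_partition",
    "write_edge_list",
    "read_streamlines",
    "read_config",
]

_SYMMETRY_TOL = 1e-8


def read_matrix(path) -> np.ndarray:
    """A symmetric matrix from TSV (no header).

    Non-square input and NaN cells are errors; asymmetry beyond 1e-8 is an
    error, below it the matrix is symmetrized; a nonzero diagonal is zeroed
    with a warning.
    """
    m = pd.read_csv(path, sep=r"\s+", header=None).to_numpy(dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataError(f"{path}: matrix is {m.shape[0]}x{m.shape[1]}, not square")
    if np.isnan(m).any():
        pos = list(zip(*np.nonzero(np.isnan(m))))[:10]
        raise DataError(f"{path}: NaN cells at positions {pos}")
    if np.max(np.abs(m - m.T)) > _SYMMETRY_TOL:
        raise DataError(f"{path}: matrix is asymmetric beyond tolerance {_SYMMETRY_TOL}")
    m = (m + m.T) / 2.0
    if np.any(np.diag(m) != 0):
        warnings.warn(f"{path}: nonzero diagonal zeroed by convention", stacklevel=2)
        np.fill_diagonal(m, 0.0)
    return m


def write_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.10g")


def write_node_table(nodes: NodeSet, path) -> None:
    nodes.to_dataframe().to_csv(path, sep="\t", index=False)


def read_node_table(path, sphere_radius: float = 5.0) -> NodeSet:
    df = pd.read_csv(path, sep="\t")
    required = {"node_id", "x", "y", "z", "label"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: node table needs columns {sorted(required)}")
    df = df.sort_values("node_id")
    if not np.array_equal(df["node_id"].to_numpy(), np.arange(len(df))):
        raise DataError(f"{path}: node ids must be unique and contiguous from 0")
    return NodeSet(
        coordinates=df[["x", "y", "z"]].to_numpy(dtype=float),
        labels=tuple(df["label"].astype(str)),
        sphere_radius=sphere_radius,
    )


def write_timeseries(ts: np.ndarray, path, node_ids=None) -> None:
    ts = np.asarray(ts)
    cols = node_ids if node_ids is not None else range(ts.shape[1])
    pd.DataFrame(ts, columns=[str(c) for c in cols]).to_csv(path, sep="\t", index=False)


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_partition(partition: Partition, path) -> None:
    pd.DataFrame(
        {"node_id": np.arange(partition.n_nodes), "module_id": partition.labels}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path) -> Partition:
    df = pd.read_csv(path, sep="\t").sort_values("node_id")
    return Partition(df["module_id"].to_numpy())


def write_edge_list(mask: np.ndarray, path) -> None:
    i, j = np.nonzero(np.triu(np.asarray(mask, dtype=bool), k=1))
    pd.DataFrame({"i": i, "j": j}).to_csv(path, sep="\t", index=False)


def read_streamlines(path) -> list[Streamline]:
    """Streamlines from the whitespace point-list format."""
    blocks: list[list[list[float]]] = [[]]
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            if blocks[-1]:
                blocks.append([])
            continue
        vals = [float(v) for v in line.split()]
        if len(vals) not in (3, 4, 5):
            raise DataError(f"{path}: streamline point lines need 3-5 columns, got {len(vals)}")
        blocks[-1].append(vals)
    out = []
    for block in blocks:
        if not block:
            continue
        arr = np.asarray(block)
        fa = arr[:, 3] if arr.shape[1] > 3 else None
        md = arr[:, 4] if arr.shape[1] > 4 else None
        out.append(Streamline(points=arr[:, :3], fa=fa, md=md))
    return out


def read_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataError(f"{path}: config must be a YAML mapping")
    return data
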