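"""Delimited-text I/O for rasters, traces, positions and edge lists.

Rasters and traces are comma-delimited with a header row of neuron ids and
one row per timepoint.  Positions carry columns neuron_id, x_um, y_um.
Edge lists carry columns i, j with i < j.  All round-trips are lossless
for the types they carry.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_raster", "read_raster", "write_traces", "read_traces",
    "write_positions", "read_positions", "check_raster_positions",
    "write_edge_list", "read_edge_list",
]


def write_raster(path, raster, neuron_ids=None) -> None:
    raster = np.asarray(raster)
    ids = np.arange(raster.shape[1]) if neuron_ids is None else neuron_ids
    pd.DataFrame(raster, columns=ids).to_csv(path, index=False)


def read_raster(path):
    """Read a binary raster; returns (matrix, neuron_ids).

    Non-binary entries are a format error naming the offending timepoint
    row and neuron column.
    """
    df = pd.read_csv(path)
    mat = df.to_numpy()
    bad = ~np.isin(mat, (0, 1))
    if bad.any():
        t, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary value {mat[t, c]!r} at timepoint row "
            f"{t} (file line {t + 2}), neuron column '{df.columns[c]}'"
        )
    return mat.astype(np.int8), np.array([int(c) for c in df.columns])


def write_traces(path, traces, neuron_ids=None) -> None:
    traces = np.asarray(traces, dtype=float)
    ids = np.arange(traces.shape[1]) if neuron_ids is None else neuron_ids
    pd.DataFrame(traces, columns=ids).to_csv(path, index=False)


def read_traces(path):
    df = pd.read_csv(path)
    mat = df.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        t, c = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"{path}: non-finite value at timepoint row {t} "
            f"(file line {t + 2}), neuron column '{df.columns[c]}'"
        )
    if (mat < 0).any():
        t, c = np.argwhere(mat < 0)[0]
        raise ValueError(
            f"{path}: negative trace value at timepoint row {t}, "
            f"neuron column '{df.columns[c]}'"
        )
    return mat, np.array([int(c) for c in df.columns])


def write_positions(path, positions: pd.DataFrame) -> None:
    positions[["neuron_id", "x_um", "y_um"]].to_csv(path, index=False)


def read_positions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"neuron_id", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["neuron_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate neuron ids")
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinates")
    return df


def check_raster_positions(neuron_ids, positions: pd.DataFrame) -> None:
    """Raster columns and position rows must describe the same neurons."""
    raster_ids = set(int(i) for i in neuron_ids)
    pos_ids = set(int(i) for i in positions["neuron_id"])
    if raster_ids != pos_ids:
        only_r = sorted(raster_ids - pos_ids)[:5]
        only_p = sorted(pos_ids - raster_ids)[:5]
        raise ValueError(
            "raster/positions neuron id mismatch: "
            f"raster-only {only_r}, positions-only {only_p}"
        )


def write_edge_list(path, graph) -> None:
    edges = sorted((min(u, v), max(u, v)) for u, v in graph.edges)
    pd.DataFrame(edges, columns=["i", "j"]).to_csv(path, index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"i", "j"} <= set(df.columns):
        raise ValueError(f"{path}: edge list needs columns i, j")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
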