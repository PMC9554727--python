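"""Trajectory file I/O.

CSV is long-format with header ``cell_id,frame,t,x,y[,species]``; HDF5
stores ``/positions [N, L, 2]``, ``/times [L]`` and optionally
``/labels [N]``.  Reads validate that the time grid is uniform.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import TrajectoryData

_CSV_COLS = ["cell_id", "frame", "t", "x", "y"]


def write_trajectory(data: TrajectoryData, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "csv":
        n, L = data.n_cells, data.n_frames
        df = pd.DataFrame({
            "cell_id": np.repeat(np.arange(n), L),
            "frame": np.tile(np.arange(L), n),
            "t": np.tile(data.times, n),
            "x": data.positions[:, :, 0].ravel(),
            "y": data.positions[:, :, 1].ravel(),
        })
        if data.labels is not None:
            df["species"] = np.repeat(np.asarray(data.labels).astype(str), L)
        df.to_csv(path, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=data.positions)
            f.create_dataset("times", data=data.times)
            if data.labels is not None:
                f.create_dataset(
                    "labels", data=np.asarray(data.labels).astype("S"))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_trajectory(path) -> TrajectoryData:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            positions = f["positions"][...]
            times = f["times"][...]
            labels = f["labels"][...].astype(str) if "labels" in f else None
        return TrajectoryData(positions=positions, times=times, labels=labels)
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    df = df.sort_values(["cell_id", "frame"], kind="mergesort")
    cells = df["cell_id"].unique()
    frames = np.sort(df["frame"].unique())
    n, L = len(cells), len(frames)
    if len(df) != n * L:
        raise ValueError("trajectory table is not a complete (cell, frame) grid")
    positions = np.empty((n, L, 2))
    positions[:, :, 0] = df["x"].to_numpy().reshape(n, L)
    positions[:, :, 1] = df["y"].to_numpy().reshape(n, L)
    times = df["t"].to_numpy().reshape(n, L)[0]
    if np.max(np.abs(df["t"].to_numpy().reshape(n, L) - times)) > 0:
        raise ValueError("inconsistent time stamps across cells")
    labels = None
    if "species" in df.columns:
        labels = df["species"].to_numpy().reshape(n, L)[:, 0].astype(str)
    return TrajectoryData(positions=positions, times=times, labels=labels)
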