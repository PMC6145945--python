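"""Trajectory CSV dialect and JSON sidecars.

Trajectories travel as comma-separated UTF-8 text with a mandatory header
``frame,t_ms,x_nm,y_nm`` ('.' decimal, 0-based frames, ms/nm units).  A
JSON sidecar (same stem, ``.meta.json``) carries the config echo, seed and
any simulation ground truth.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import RawTrajectory

log = logging.getLogger("chimotor")

TRAJ_COLUMNS = ["frame", "t_ms", "x_nm", "y_nm"]


def save_trajectory(traj: RawTrajectory, path) -> Path:
    """Write trajectory CSV plus a .meta.json sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(traj), dtype=int),
            "t_ms": traj.t_ms,
            "x_nm": traj.x_nm,
            "y_nm": traj.y_nm,
        }
    )
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".meta.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(traj.meta), fh, indent=1)
    return path


def load_trajectory(path) -> RawTrajectory:
    """Read a trajectory CSV (and its sidecar if present).

    Malformed rows are reported with line numbers; rows out of time order
    are re-sorted with a warning; a non-uniform time grid is rejected
    naming the first offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file") from None
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must be {TRAJ_COLUMNS}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    bad = df[TRAJ_COLUMNS].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: malformed rows at lines {rows[:10]}")
    t = df["t_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: rows out of time order; re-sorting", stacklevel=2)
        df = df.sort_values("t_ms", kind="stable").reset_index(drop=True)
    meta = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = json.load(fh)
    return RawTrajectory(
        t_ms=df["t_ms"].to_numpy(dtype=float),
        x_nm=df["x_nm"].to_numpy(dtype=float),
        y_nm=df["y_nm"].to_numpy(dtype=float),
        meta=meta,
    )


def save_tiff_stack(stack: np.ndarray, path) -> Path:
    """Write an image stack as multi-page TIFF."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack)
    return path


def load_tiff_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(Path(path))


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays for json.dump."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
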