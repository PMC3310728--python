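"""Trajectory and configuration file I/O.

Two trajectory dialects, loss-lessly interconvertible:

* CSV with header ``time_s,ped_id,x_m,y_m,direction`` (optional
  ``v0_mps``), one row per pedestrian per frame, with the corridor
  geometry embedded in a ``#`` comment line of JSON;
* HDF5 with datasets ``/times``, ``/positions`` (frame x pedestrian x 2),
  ``/directions``, ``/ids`` and optional ``/v0``, geometry as root
  attributes.

Configuration files are JSON mirroring the parameter dataclass field names
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import CorridorGeometry
from .trajectory import TrajectorySet

__all__ = ["read_trajectories", "write_trajectories", "read_config_file"]

CSV_COLUMNS = ["time_s", "ped_id", "x_m", "y_m", "direction"]


class TrajectoryFormatError(ValueError):
    """Structurally invalid trajectory file."""


def write_trajectories(traj: TrajectorySet, path) -> None:
    """Write a TrajectorySet to ``path`` (dialect chosen by suffix)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(traj, path)
    elif path.suffix == ".csv":
        _write_csv(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {path.suffix!r} (use .csv or .h5)")


def read_trajectories(path, geometry: CorridorGeometry | None = None) -> TrajectorySet:
    """Read a TrajectorySet; ``geometry`` overrides the embedded one."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path, geometry)
    if path.suffix == ".csv":
        return _read_csv(path, geometry)
    raise ValueError(f"unknown trajectory format {path.suffix!r} (use .csv or .h5)")


def _write_hdf5(traj: TrajectorySet, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("positions", data=traj.positions)
        f.create_dataset("directions", data=traj.directions)
        f.create_dataset("ids", data=traj.ids)
        if traj.v0 is not None:
            f.create_dataset("v0", data=traj.v0)
        f.attrs["r_inner"] = traj.geometry.r_inner
        f.attrs["r_outer"] = traj.geometry.r_outer


def _read_hdf5(path: Path, geometry: CorridorGeometry | None) -> TrajectorySet:
    with h5py.File(path, "r") as f:
        for name in ("times", "positions", "directions"):
            if name not in f:
                raise TrajectoryFormatError(f"missing dataset /{name} in {path}")
        geom = geometry or CorridorGeometry(float(f.attrs["r_inner"]),
                                            float(f.attrs["r_outer"]))
        return TrajectorySet(
            times=f["times"][()],
            positions=f["positions"][()],
            directions=f["directions"][()],
            geometry=geom,
            v0=f["v0"][()] if "v0" in f else None,
            ids=f["ids"][()] if "ids" in f else None,
        )


def _write_csv(traj: TrajectorySet, path: Path) -> None:
    T, N = traj.n_frames, traj.n_pedestrians
    frame = pd.DataFrame({
        "time_s": np.repeat(traj.times, N),
        "ped_id": np.tile(traj.ids, T),
        "x_m": traj.positions[:, :, 0].ravel(),
        "y_m": traj.positions[:, :, 1].ravel(),
        "direction": np.tile(traj.directions, T),
    })
    if traj.v0 is not None:
        frame["v0_mps"] = np.tile(traj.v0, T)
    header = "# " + json.dumps({"r_inner": traj.geometry.r_inner,
                                "r_outer": traj.geometry.r_outer})
    with open(path, "w") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, index=False, float_format="%.9g")


def _read_csv(path: Path, geometry: CorridorGeometry | None) -> TrajectorySet:
    with open(path) as fh:
        first = fh.readline()
    geom = geometry
    if first.startswith("#"):
        try:
            meta = json.loads(first.lstrip("# "))
            geom = geometry or CorridorGeometry(meta["r_inner"], meta["r_outer"])
        except (json.JSONDecodeError, KeyError) as exc:
            raise TrajectoryFormatError(f"bad geometry comment in {path}: {exc}")
    if geom is None:
        raise TrajectoryFormatError(f"{path} carries no geometry; pass one explicitly")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path} lacks columns {missing}")
    times = np.array(sorted(df["time_s"].unique()))
    ids = np.array(sorted(df["ped_id"].unique()))
    T, N = times.size, ids.size
    if len(df) != T * N:
        counts = df.groupby("time_s")["ped_id"].nunique()
        bad_t = counts.index[counts != N]
        t0 = float(bad_t[0]) if len(bad_t) else float("nan")
        present = set(df.loc[df.time_s == t0, "ped_id"])
        absent = sorted(set(ids.tolist()) - present)
        raise TrajectoryFormatError(
            f"{path}: frame t={t0} is missing pedestrian(s) {absent}")
    df = df.sort_values(["time_s", "ped_id"])
    positions = np.stack([df["x_m"].to_numpy().reshape(T, N),
                          df["y_m"].to_numpy().reshape(T, N)], axis=-1)
    per_ped = df.iloc[:N].sort_values("ped_id")
    v0 = per_ped["v0_mps"].to_numpy() if "v0_mps" in df.columns else None
    return TrajectorySet(times=times, positions=positions,
                         directions=per_ped["direction"].to_numpy(),
                         geometry=geom, v0=v0, ids=ids)


def read_config_file(path) -> dict:
    """Read a JSON configuration file into a plain dict."""
    with open(path) as fh:
        return json.load(fh)
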