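"""Trajectory persistence: HDF5 container plus a flat CSV sidecar.

Layout of the HDF5 file::

    /series/{t_day,total_mass,dose_B,dose_H,treatment_on,clipped_mass}
    /fields/<index>/{c,v,n,a,w_B,w_H}   one group per snapshot, attr t
    attrs: config (YAML text), config_hash

Series are stored at 64-bit precision and round-trip bit-exactly; the 4D
snapshot densities are stored at 32-bit to halve file size.  The CSV
sidecar (same stem, ``.csv``) carries the time series with the fixed
schema ``t_day,total_mass,dose_B,dose_H,treatment_on``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import TrajectoryIOError
from .solver import FieldState, Trajectory

_SERIES = ("times", "mass", "dose_B", "dose_H", "treatment_on", "clipped_mass")
_FIELDS = ("c", "v", "n", "a", "w_B", "w_H")


def csv_path(path) -> Path:
    return Path(path).with_suffix(".csv")


def write_trajectory(trajectory: Trajectory, path) -> Path:
    """Write the HDF5 container and its CSV sidecar; returns the HDF5 path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = yaml.safe_dump(trajectory.config, sort_keys=True)
        f.attrs["config_hash"] = trajectory.config_hash
        g = f.create_group("series")
        for name in _SERIES:
            g.create_dataset(name, data=np.asarray(getattr(trajectory, name)))
        fields = f.create_group("fields")
        for i, snap in enumerate(trajectory.snapshots):
            sg = fields.create_group(f"{i:05d}")
            sg.attrs["t"] = snap.t
            sg.attrs["treatment_on"] = bool(snap.treatment_on)
            sg.create_dataset("c", data=snap.c.astype(np.float32), compression="gzip", shuffle=True)
            for name in _FIELDS[1:]:
                sg.create_dataset(name, data=getattr(snap, name))
    df = pd.DataFrame(
        {
            "t_day": trajectory.times,
            "total_mass": trajectory.mass,
            "dose_B": trajectory.dose_B,
            "dose_H": trajectory.dose_H,
            "treatment_on": trajectory.treatment_on.astype(int),
        }
    )
    df.to_csv(csv_path(path), index=False)
    return path


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    if not path.exists():
        raise TrajectoryIOError(f"no trajectory file at {path}")
    try:
        with h5py.File(path, "r") as f:
            series = {name: f["series"][name][...] for name in _SERIES}
            config = yaml.safe_load(f.attrs["config"])
            config_hash = str(f.attrs["config_hash"])
            snapshots = []
            snap_times = []
            for key in sorted(f["fields"].keys()):
                sg = f["fields"][key]
                snapshots.append(
                    FieldState(
                        t=float(sg.attrs["t"]),
                        c=sg["c"][...].astype(np.float64),
                        v=sg["v"][...],
                        n=sg["n"][...],
                        a=sg["a"][...],
                        w_B=sg["w_B"][...],
                        w_H=sg["w_H"][...],
                        treatment_on=bool(sg.attrs["treatment_on"]),
                    )
                )
                snap_times.append(float(sg.attrs["t"]))
    except (KeyError, OSError) as exc:
        raise TrajectoryIOError(f"cannot read trajectory {path}: {exc}") from exc
    return Trajectory(
        times=series["times"],
        mass=series["mass"],
        dose_B=series["dose_B"],
        dose_H=series["dose_H"],
        treatment_on=series["treatment_on"].astype(bool),
        clipped_mass=series["clipped_mass"],
        snapshot_times=np.asarray(snap_times),
        snapshots=snapshots,
        config=config,
        config_hash=config_hash,
    )
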