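"""Session container and file I/O.

A session bundles one trajectory with the cell roster recorded during
it, plus arena/FOV geometry and provenance metadata. On disk a session
set lives in a single HDF5 file (one group per session: trajectory
arrays, per-cell traces/events, anatomical centroids, a JSON metadata
blob). Trajectories and event trains can also be exported to / imported
from plain CSV for cross-language fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import CellRecording, DataError, Trajectory
from .synthetic import ArenaSpec, FovSpec

__all__ = [
    "SessionContainer",
    "write_sessions",
    "read_sessions",
    "export_trajectory_csv",
    "import_trajectory_csv",
    "export_events_csv",
    "import_events_csv",
]

ALLOWED_LABELS = {"A", "B", "A2", "baseline", "object", "object_moved", "post"}


@dataclass
class SessionContainer:
    label: str
    traj: Trajectory
    cells: list[CellRecording]
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    fov: FovSpec = field(default_factory=FovSpec)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ALLOWED_LABELS:
            raise DataError(
                f"session label {self.label!r} not in {sorted(ALLOWED_LABELS)}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.cells])


def write_sessions(path: str | Path, sessions: list[SessionContainer]) -> None:
    """Write a session set to one HDF5 file (lossless round trip)."""
    with h5py.File(path, "w") as f:
        for k, s in enumerate(sessions):
            g = f.create_group(f"session_{k:02d}")
            g.attrs["label"] = s.label
            g.attrs["meta"] = json.dumps(
                {
                    "arena_side": s.arena.side_length,
                    "arena_wall": s.arena.wall_height,
                    "fov_width": s.fov.width,
                    "fov_height": s.fov.height,
                    **s.meta,
                }
            )
            tg = g.create_group("trajectory")
            tg.create_dataset("t", data=s.traj.t)
            tg.create_dataset("x", data=s.traj.x)
            tg.create_dataset("y", data=s.traj.y)
            cg = g.create_group("cells")
            cg.create_dataset("cell_id", data=[c.cell_id for c in s.cells])
            cg.create_dataset("centroid", data=s.centroids() if s.cells else np.empty((0, 2)))
            cg.create_dataset(
                "dff", data=np.array([c.dff for c in s.cells]) if s.cells else np.empty((0, 0))
            )
            ev = cg.create_group("events")
            for c in s.cells:
                eg = ev.create_group(str(c.cell_id))
                eg.create_dataset("t", data=c.events_t)
                eg.create_dataset("amplitude", data=c.events_amp)


def read_sessions(path: str | Path) -> list[SessionContainer]:
    """Read a session set written by :func:`write_sessions`."""
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            meta = json.loads(g.attrs["meta"])
            if "trajectory" not in g:
                raise DataError(f"{key}: missing 'trajectory' group")
            if "cells" not in g or "events" not in g["cells"]:
                raise DataError(f"{key}: missing 'cells/events' table")
            tg = g["trajectory"]
            traj = Trajectory(t=tg["t"][:], x=tg["x"][:], y=tg["y"][:])
            cg = g["cells"]
            ids = cg["cell_id"][:]
            cents = cg["centroid"][:]
            dff = cg["dff"][:]
            cells = []
            for i, cid in enumerate(ids):
                eg = cg["events"][str(int(cid))]
                cells.append(
                    CellRecording(
                        cell_id=int(cid),
                        dff=dff[i] if dff.size else np.array([]),
                        events_t=eg["t"][:],
                        events_amp=eg["amplitude"][:],
                        centroid=tuple(cents[i]),
                    )
                )
            out.append(
                SessionContainer(
                    label=str(g.attrs["label"]),
                    traj=traj,
                    cells=cells,
                    arena=ArenaSpec(meta["arena_side"], meta["arena_wall"]),
                    fov=FovSpec(meta["fov_width"], meta["fov_height"]),
                    meta={
                        k: v
                        for k, v in meta.items()
                        if k not in ("arena_side", "arena_wall", "fov_width", "fov_height")
                    },
                )
            )
    return out


def export_trajectory_csv(path: str | Path, traj: Trajectory) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y}).to_csv(path, index=False)


def import_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df:
            raise DataError(f"trajectory CSV missing column {col!r}")
    return Trajectory(t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy())


def export_events_csv(path: str | Path, cells: list[CellRecording]) -> None:
    rows = [
        {"cell_id": c.cell_id, "t": t, "amplitude": a}
        for c in cells
        for t, a in zip(c.events_t, c.events_amp)
    ]
    pd.DataFrame(rows, columns=["cell_id", "t", "amplitude"]).to_csv(path, index=False)


def import_events_csv(path: str | Path, centroids: dict[int, tuple[float, float]] | None = None):
    """Events CSV → list of CellRecording (empty ΔF/F traces)."""
    df = pd.read_csv(path)
    for col in ("cell_id", "t", "amplitude"):
        if col not in df:
            raise DataError(f"events CSV missing column {col!r}")
    cells = []
    for cid, grp in df.groupby("cell_id"):
        cells.append(
            CellRecording(
                cell_id=int(cid),
                dff=np.array([]),
                events_t=grp["t"].to_numpy(),
                events_amp=grp["amplitude"].to_numpy(),
                centroid=tuple(centroids.get(int(cid), (np.nan, np.nan))) if centroids else (np.nan, np.nan),
            )
        )
    return cells
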