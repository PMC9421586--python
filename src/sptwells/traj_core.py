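"""Trajectory data model and I/O.

The universal input of every analysis in this package is an ensemble of
short 2-D single-particle trajectories sharing one acquisition interval
``dt``.  Positions are stored in micrometres and times in seconds; readers
convert from nanometres or frame indices on the way in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryEnsemble",
    "Displacements",
    "read_trajectories",
    "write_trajectories",
]

logger = logging.getLogger(__name__)

_REL_TOL = 1e-6  # relative tolerance on uniformity of the sampling interval


@dataclass(frozen=True)
class Trajectory:
    """One trajectory: strictly increasing times and matching 2-D positions.

    Parameters
    ----------
    id : object
        Opaque identifier (whatever the source table used).
    t : ndarray, shape (M,)
        Observation times in seconds, strictly increasing, uniformly spaced.
    xy : ndarray, shape (M, 2)
        Positions in micrometres.
    """

    id: object
    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise ValueError("t must be (M,) and xy (M, 2)")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates")
        if t.size >= 2:
            gaps = np.diff(t)
            if np.any(gaps <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(gaps - gaps[0]) > _REL_TOL * gaps[0]):
                raise ValueError("non-uniform sampling inside one trajectory")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return self.t.size


@dataclass
class Displacements:
    """Flat arrays of consecutive-point displacements of an ensemble.

    ``origins[i]`` is the starting position of displacement i, ``dxy[i]``
    the step vector over one interval ``dt``, ``origin_t[i]`` its starting
    time and ``traj_index[i]`` the index of the source trajectory.
    """

    origins: np.ndarray  # (n, 2) μm
    dxy: np.ndarray  # (n, 2) μm
    origin_t: np.ndarray  # (n,) s
    traj_index: np.ndarray  # (n,) int
    dt: float

    @property
    def speeds(self) -> np.ndarray:
        """Instantaneous speeds |ΔX|/Δt in μm/s."""
        return np.hypot(self.dxy[:, 0], self.dxy[:, 1]) / self.dt

    def __len__(self) -> int:
        return self.origins.shape[0]


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories sharing one acquisition interval.

    Attributes
    ----------
    trajectories : list of Trajectory
    dt : float
        Acquisition interval Δt in seconds.
    """

    trajectories: list[Trajectory]
    dt: float
    _disp_cache: Displacements | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def n_points(self) -> int:
        return sum(len(tr) for tr in self.trajectories)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in μm enclosing all points."""
        if not self.trajectories:
            raise ValueError("empty ensemble has no bbox")
        pts = self.points()
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )

    def points(self) -> np.ndarray:
        """All points stacked, shape (Σ Mi, 2)."""
        if not self.trajectories:
            return np.empty((0, 2))
        return np.concatenate([tr.xy for tr in self.trajectories])

    def displacements(self) -> Displacements:
        """One displacement per consecutive point pair (count = Σ (Mi − 1))."""
        if self._disp_cache is not None:
            return self._disp_cache
        origins, dxy, ot, ti = [], [], [], []
        for i, tr in enumerate(self.trajectories):
            if len(tr) < 2:
                continue
            origins.append(tr.xy[:-1])
            dxy.append(np.diff(tr.xy, axis=0))
            ot.append(tr.t[:-1])
            ti.append(np.full(len(tr) - 1, i, dtype=np.intp))
        if origins:
            disp = Displacements(
                np.concatenate(origins),
                np.concatenate(dxy),
                np.concatenate(ot),
                np.concatenate(ti),
                self.dt,
            )
        else:
            disp = Displacements(
                np.empty((0, 2)), np.empty((0, 2)), np.empty(0), np.empty(0, dtype=np.intp), self.dt
            )
        self._disp_cache = disp
        return disp

    def subset(self, indices: Iterable[int]) -> "TrajectoryEnsemble":
        trs = [self.trajectories[i] for i in indices]
        return TrajectoryEnsemble(trs, self.dt)


def _split_at_gaps(
    frames: np.ndarray, xy: np.ndarray, tid: object, dt: float
) -> tuple[list[Trajectory], int]:
    """Split a per-id point series at missed frames; drop singletons."""
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    xy = xy[order]
    breaks = np.flatnonzero(np.diff(frames) != 1) + 1
    out = []
    n_dropped = 0
    for k, chunk in enumerate(np.split(np.arange(frames.size), breaks)):
        if chunk.size < 2:
            n_dropped += 1
            continue
        sub_id = tid if len(breaks) == 0 else f"{tid}#{k}"
        out.append(Trajectory(sub_id, frames[chunk] * dt, xy[chunk]))
    return out, n_dropped


def read_trajectories(
    path,
    format: str = "csv",
    dt: float | None = None,
    unit: str = "um",
) -> TrajectoryEnsemble:
    """Read a trajectory table into a :class:`TrajectoryEnsemble`.

    Parameters
    ----------
    path : str or file-like
        CSV file with a header row.
    format : {"csv", "trackmate_csv"}
        ``csv`` expects columns ``traj``, ``frame`` or ``t``, ``x``, ``y``;
        ``trackmate_csv`` expects a TrackMate spots export with columns
        ``TRACK_ID``, ``FRAME``, ``POSITION_X``, ``POSITION_Y``.
    dt : float, optional
        Acquisition interval in seconds.  Required when the time column
        holds frame indices; when a ``t`` column in seconds is present, dt
        is inferred unless given.
    unit : {"um", "nm"}
        Unit of the position columns; nm inputs are converted to μm.

    Notes
    -----
    Points are grouped by id and sorted by time.  A missing frame breaks a
    trajectory into separate fragments (blinking is not bridged) and
    fragments with a single point are discarded with a logged count.
    """
    df = pd.read_csv(path)
    if format == "trackmate_csv":
        cols = {"TRACK_ID": "traj", "FRAME": "frame", "POSITION_X": "x", "POSITION_Y": "y"}
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"TrackMate export lacks columns: {missing}")
        # TrackMate prepends up to three non-numeric header rows
        df = df[cols.keys()].rename(columns=cols)
        df = df.apply(pd.to_numeric, errors="coerce").dropna()
    elif format == "csv":
        if "traj" not in df.columns or "x" not in df.columns or "y" not in df.columns:
            raise ValueError("CSV must contain columns traj, frame or t, x, y")
        if "frame" not in df.columns and "t" not in df.columns:
            raise ValueError("CSV must contain a frame or t column")
    else:
        raise ValueError(f"unknown format {format!r}")

    scale = {"um": 1.0, "nm": 1e-3}[unit]

    if "frame" in df.columns:
        if dt is None:
            raise ValueError("dt is required when times are frame indices")
        frames_all = np.asarray(df["frame"], dtype=float)
        fr_round = np.rint(frames_all)
        if np.any(np.abs(frames_all - fr_round) > 1e-9):
            raise ValueError("frame column must hold integers")
        df = df.assign(_frame=fr_round.astype(np.int64))
    else:
        t = np.asarray(df["t"], dtype=float)
        if dt is None:
            gaps = np.concatenate(
                [np.diff(np.sort(g["t"].to_numpy())) for _, g in df.groupby("traj") if len(g) > 1]
            )
            gaps = gaps[gaps > 0]
            if gaps.size == 0:
                raise ValueError("cannot infer dt from single-point trajectories")
            dt = float(np.min(gaps))
        fr = t / dt
        fr_round = np.rint(fr)
        if np.any(np.abs(fr - fr_round) > _REL_TOL * np.maximum(1.0, np.abs(fr))):
            raise ValueError("time stamps are not integer multiples of dt")
        df = df.assign(_frame=fr_round.astype(np.int64))

    trajectories: list[Trajectory] = []
    n_dropped = 0
    for tid, g in df.groupby("traj", sort=False):
        frames = g["_frame"].to_numpy()
        xy = g[["x", "y"]].to_numpy(dtype=float) * scale
        frags, dropped = _split_at_gaps(frames, xy, tid, dt)
        n_dropped += dropped
        trajectories.extend(frags)
    if n_dropped:
        logger.info("dropped %d single-point fragments", n_dropped)
    return TrajectoryEnsemble(trajectories, float(dt))


def write_trajectories(ens: TrajectoryEnsemble, path) -> None:
    """Write the standard CSV (traj, frame, t, x, y) for an ensemble."""
    rows = []
    for tr in ens.trajectories:
        frames = np.rint(tr.t / ens.dt).astype(np.int64)
        rows.append(
            pd.DataFrame({"traj": tr.id, "frame": frames, "t": tr.t, "x": tr.xy[:, 0], "y": tr.xy[:, 1]})
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def ensemble_from_arrays(
    positions: Sequence[np.ndarray], dt: float, t0: float | Sequence[float] = 0.0, ids=None
) -> TrajectoryEnsemble:
    """Build an ensemble from a list of (M_i, 2) position arrays."""
    t0s = np.broadcast_to(np.asarray(t0, dtype=float), (len(positions),))
    trs = []
    for i, xy in enumerate(positions):
        xy = np.asarray(xy, dtype=float)
        if len(xy) < 2:
            continue
        tid = i if ids is None else ids[i]
        trs.append(Trajectory(tid, t0s[i] + dt * np.arange(len(xy)), xy))
    return TrajectoryEnsemble(trs, dt)
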