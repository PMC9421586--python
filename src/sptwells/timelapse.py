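"""Sliding-window well detection and stability tracking.

Recordings are split into (by default non-overlapping) time windows of
fixed duration; wells detected in consecutive windows are considered the
same when their centers lie within a matching distance (default 200 nm).
A track's stability duration is τ = t_r − t_q, the span between the first
and last detection windows; with bridging enabled a well that disappears
for a limited number of windows and then reappears nearby is kept for the
whole period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .traj_core import Trajectory, TrajectoryEnsemble
from .wells import PotentialWell

__all__ = ["WellTrack", "window_split", "track_wells", "timelapse_wells"]

logger = logging.getLogger(__name__)


@dataclass
class WellTrack:
    """One well followed over consecutive time windows."""

    windows: list[tuple[int, PotentialWell]]  # (window index, detection)
    window_duration: float  # s
    step: float  # window start-to-start step, s
    bridged: set[int] = field(default_factory=set)  # gap windows counted as present

    @property
    def t_q(self) -> float:
        """Start time of the first detection window (s)."""
        return self.windows[0][0] * self.step

    @property
    def t_r(self) -> float:
        """Start time of the last detection window (s)."""
        return self.windows[-1][0] * self.step

    @property
    def tau(self) -> float:
        """Stability duration τ = t_r − t_q (s)."""
        return self.t_r - self.t_q

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def window_split(
    ens: TrajectoryEnsemble, window: float, overlap: float = 0.0
) -> list[TrajectoryEnsemble]:
    """Clip an ensemble into time windows of the given duration.

    Windows start at multiples of ``window − overlap`` from the first
    recorded time.  A trajectory spanning a boundary contributes its
    within-window fragment to each window it crosses; empty windows are
    retained so indexing matches window start times.
    """
    if not (window > overlap >= 0):
        raise ValueError("need window > overlap >= 0")
    t_all = np.concatenate([tr.t for tr in ens.trajectories])
    t0, t1 = float(t_all.min()), float(t_all.max())
    step = window - overlap
    span = t1 - t0
    if window >= span + ens.dt:
        logger.warning("window longer than the recording; single window")
        return [ens]
    n_win = int(np.floor((span - window) / step)) + 1
    if t0 + (n_win - 1) * step + window <= t1:
        n_win += 1
    out = []
    for w in range(n_win):
        lo = t0 + w * step
        hi = lo + window
        trs = []
        for tr in ens.trajectories:
            sel = (tr.t >= lo) & (tr.t < hi)
            if sel.sum() >= 2:
                trs.append(Trajectory(tr.id, tr.t[sel], tr.xy[sel]))
        out.append(TrajectoryEnsemble(trs, ens.dt))
    return out


def track_wells(
    per_window: Sequence[Sequence[PotentialWell]],
    match_dist: float = 0.2,
    bridge: bool = True,
    max_gap: int = 1,
    window: float = 20.0,
    overlap: float = 0.0,
) -> list[WellTrack]:
    """Link per-window well detections into stability tracks.

    Matching between a window and the currently active tracks is greedy by
    increasing center distance under ``match_dist`` (so the result does not
    depend on well list order).  When two candidates compete for one track
    the nearer center wins and the other starts a new track.  With
    ``bridge`` enabled, a track missing for up to ``max_gap`` consecutive
    windows may be resumed; the gap windows are recorded as bridged
    presence.
    """
    step = window - overlap
    tracks: list[WellTrack] = []
    active: list[WellTrack] = []
    for w, wells in enumerate(per_window):
        allowed_gap = max_gap if bridge else 0
        live = [tr for tr in active if w - tr.windows[-1][0] <= allowed_gap + 1]
        pairs = []
        for ti, tr in enumerate(live):
            cx, cy = tr.windows[-1][1].center
            for wi, well in enumerate(wells):
                d = float(np.hypot(well.center[0] - cx, well.center[1] - cy))
                if d < match_dist:
                    pairs.append((d, ti, wi))
        pairs.sort()
        used_t: set[int] = set()
        used_w: set[int] = set()
        for d, ti, wi in pairs:
            if ti in used_t or wi in used_w:
                continue
            tr = live[ti]
            last_w = tr.windows[-1][0]
            tr.bridged.update(range(last_w + 1, w))
            tr.windows.append((w, wells[wi]))
            used_t.add(ti)
            used_w.add(wi)
        for wi, well in enumerate(wells):
            if wi not in used_w:
                nt = WellTrack([(w, well)], window, step)
                tracks.append(nt)
        active = [tr for tr in tracks if w - tr.windows[-1][0] <= allowed_gap]
    return tracks


def timelapse_wells(
    ens: TrajectoryEnsemble,
    detect: Callable[[TrajectoryEnsemble], list[PotentialWell]],
    window: float = 20.0,
    overlap: float = 0.0,
    match_dist: float = 0.2,
    bridge: bool = True,
    max_gap: int = 1,
) -> list[WellTrack]:
    """Detect wells per window and link them into tracks."""
    wins = window_split(ens, window, overlap)
    per_window = []
    for we in wins:
        per_window.append(detect(we) if len(we) else [])
    return track_wells(per_window, match_dist, bridge, max_gap, window, overlap)
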