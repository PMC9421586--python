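"""Mixed-motion (lysosome-style) analyses.

Lysosome-like organelles alternate between slow, locally confined motion
and fast directed runs.  This module provides:

* a two-exponential fit of the instantaneous-speed distribution
  f(v) = A·exp(−v/v₀) + B·exp(−v/v₁), separating slow and fast regimes;
* extraction of high-density regions (HDRs) as 95% confidence ellipses
  around density hot spots, with iterative merging of overlaps;
* an inter-HDR network linked by trajectories crossing from one region to
  another within one or two frames, with a Rayleigh fit of the inter-node
  speeds as a diffusion null;
* transient-confinement detection along single trajectories with
  Ornstein-Uhlenbeck characterization of each confined period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import kstest, rayleigh

from .netgraph import NetworkGraph, NetworkNode
from .traj_core import TrajectoryEnsemble
from .wells import Ellipse, confidence_ellipse, ou_mle

__all__ = [
    "VelocityMixtureFit",
    "HDRegion",
    "ConfinementEvent",
    "fit_velocity_mixture",
    "extract_hdrs",
    "hdr_network",
    "detect_confinements",
    "fit_exponential_durations",
]

logger = logging.getLogger(__name__)


@dataclass
class VelocityMixtureFit:
    """Two-exponential fit of a speed histogram."""

    amp_slow: float  # A
    amp_fast: float  # B
    v0: float  # slow scale, μm/s
    v1: float  # fast scale, μm/s (v1 > v0)
    r2: float
    converged: bool


def _two_exp(v, A, v0, B, v1):
    return A * np.exp(-v / v0) + B * np.exp(-v / v1)


def fit_velocity_mixture(speeds: np.ndarray, bins: int | str = 60) -> VelocityMixtureFit:
    """Fit f(v) = A e^{−v/v₀} + B e^{−v/v₁} to the normalized speed histogram.

    Initialization comes from single-exponential fits to the lower and
    upper halves of the sample.  On non-convergence a single-exponential
    fallback is flagged (v₀ = v₁).
    """
    speeds = np.asarray(speeds, dtype=float)
    speeds = speeds[np.isfinite(speeds) & (speeds >= 0)]
    if speeds.size < 100:
        raise ValueError("need at least 100 speeds")
    if np.ptp(speeds) == 0:
        raise ValueError("zero-variance speed sample")
    hist, edges = np.histogram(speeds, bins=bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    med = np.median(speeds)
    lo = speeds[speeds <= med]
    hi = speeds[speeds > med]
    v0_init = max(float(lo.mean()), 1e-4)
    v1_init = max(float(hi.mean()), 2 * v0_init)
    p0 = [hist.max(), v0_init, 0.1 * hist.max(), v1_init]
    try:
        popt, _ = curve_fit(
            _two_exp,
            centers,
            hist,
            p0=p0,
            bounds=([0, 1e-6, 0, 1e-6], [np.inf] * 4),
            maxfev=20000,
        )
        A, v0, B, v1 = popt
        if v0 > v1:
            A, v0, B, v1 = B, v1, A, v0
        pred = _two_exp(centers, A, v0, B, v1)
        ss_res = float(np.sum((hist - pred) ** 2))
        ss_tot = float(np.sum((hist - hist.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return VelocityMixtureFit(float(A), float(B), float(v0), float(v1), r2, True)
    except RuntimeError:
        logger.warning("two-exponential fit failed; single-exponential fallback")
        tau = float(speeds.mean())

        def one_exp(v, A):
            return A * np.exp(-v / tau)

        popt, _ = curve_fit(one_exp, centers, hist, p0=[hist.max()])
        pred = one_exp(centers, *popt)
        ss_tot = float(np.sum((hist - hist.mean()) ** 2))
        r2 = 1.0 - float(np.sum((hist - pred) ** 2)) / ss_tot if ss_tot > 0 else 0.0
        return VelocityMixtureFit(float(popt[0]), 0.0, tau, tau, r2, False)


# ---------------------------------------------------------------------------
# high-density regions


@dataclass
class HDRegion:
    """A high-density region: its member points and 95% confidence ellipse."""

    id: int
    boundary: Ellipse
    points: np.ndarray


def extract_hdrs(
    ens: TrajectoryEnsemble,
    coarse_dx: float = 0.48,
    top_pct: float = 5.0,
    fine_dx: float = 0.2,
    level: float = 0.8,
    conf: float = 95.0,
) -> list[HDRegion]:
    """Extract high-density regions as non-overlapping confidence ellipses.

    Steps: (1) coarse density map; (2) keep the top ``top_pct``% bins,
    suppressing any kept bin within two squares of a denser one; (3) per
    kept bin, a 5×5 refined map of bin size ``fine_dx`` centered on it;
    (4) points in refined bins above ``level`` of the local maximum define
    the region and its ellipse; (5) overlapping ellipses are replaced by
    the ellipse of their combined points until no overlaps remain.
    """
    from .maps import Grid, density_map

    dm = density_map(ens, coarse_dx)
    vals = dm.values
    if not np.any(dm.counts > 0):
        return []
    # top percentile over the whole map (empty bins included), as a sparse
    # field should still yield every isolated hot spot
    thresh = max(np.percentile(vals, 100.0 - top_pct), np.finfo(float).tiny)
    ii, jj = np.nonzero((vals >= thresh) & (dm.counts > 0))
    order = np.argsort(vals[ii, jj])[::-1]
    kept: list[tuple[int, int]] = []
    for o in order:
        bi, bj = int(ii[o]), int(jj[o])
        if any(abs(bi - ki) <= 2 and abs(bj - kj) <= 2 for ki, kj in kept):
            continue
        kept.append((bi, bj))

    pts = ens.points()
    cx, cy = dm.grid.centers()
    regions: list[np.ndarray] = []
    for bi, bj in kept:
        c = np.array([cx[bi], cy[bj]])
        origin = c - 2.5 * fine_dx
        fine = Grid((origin[0], origin[1]), fine_dx, 5, 5)
        fi, fj, valid = fine.bin_index(pts)
        counts = np.zeros((5, 5))
        np.add.at(counts, (fi[valid], fj[valid]), 1)
        m = counts.max()
        if m <= 0:
            continue
        dense = counts > level * m
        member = np.zeros(pts.shape[0], dtype=bool)
        member[valid] = dense[fi[valid], fj[valid]]
        if member.sum() < 3:
            continue
        regions.append(pts[member])

    # iterative merging of overlapping ellipses
    def fit(ptsk):
        return confidence_ellipse(ptsk, conf)

    ells = []
    mems = []
    for m in regions:
        try:
            ells.append(fit(m))
            mems.append(m)
        except ValueError:
            continue
    merged = True
    while merged:
        merged = False
        for i in range(len(ells)):
            for j in range(i + 1, len(ells)):
                if ells[i].overlaps(ells[j]):
                    mems[i] = np.concatenate([mems[i], mems[j]])
                    ells[i] = fit(mems[i])
                    del ells[j], mems[j]
                    merged = True
                    break
            if merged:
                break
    return [HDRegion(k, e, m) for k, (e, m) in enumerate(zip(ells, mems))]


def hdr_network(
    ens: TrajectoryEnsemble, regions: list[HDRegion], max_gap_frames: int = 2
) -> tuple[NetworkGraph, dict]:
    """Link HDRs traversed by a trajectory within one or two frames.

    A link (i, j) is added when some trajectory has a point in region i and
    a point in region j at most ``max_gap_frames`` frames later.  Traversal
    speeds ‖ΔX‖/(mΔt) are collected and a Rayleigh distribution (the speed
    law of isotropic Gaussian displacement components) is fitted by maximum
    likelihood; a Kolmogorov-Smirnov p-value reports its adequacy.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    K = len(regions)
    C = np.zeros((K, K), dtype=np.int64)
    speeds = []
    for tr in ens.trajectories:
        member = np.full(len(tr), -1, dtype=np.int64)
        for r in regions:
            inside = r.boundary.contains(tr.xy)
            member[inside & (member < 0)] = r.id
        for gap in range(1, max_gap_frames + 1):
            a, b = member[:-gap], member[gap:]
            sel = (a >= 0) & (b >= 0) & (a != b)
            if gap == 2:
                sel &= member[1:-1] < 0  # strictly off-region in between
            idx = np.flatnonzero(sel)
            np.add.at(C, (a[idx], b[idx]), 1)
            for l in idx:
                d = np.hypot(*(tr.xy[l + gap] - tr.xy[l]))
                speeds.append(float(d / (gap * ens.dt)))
    nodes = [NetworkNode(r.id, r.points, r.boundary) for r in regions]
    graph = NetworkGraph(nodes, C + C.T, C, 1)
    speeds = np.asarray(speeds)
    out = {"speeds": speeds, "rayleigh_scale": np.nan, "ks_pvalue": np.nan}
    if speeds.size >= 5:
        scale = float(np.sqrt(np.mean(speeds**2) / 2.0))  # Rayleigh MLE
        ks = kstest(speeds, rayleigh(scale=scale).cdf)
        out["rayleigh_scale"] = scale
        out["ks_pvalue"] = float(ks.pvalue)
    return graph, out


# ---------------------------------------------------------------------------
# transient confinement


@dataclass
class ConfinementEvent:
    """A confined sub-trajectory and its OU characterization."""

    traj_id: object
    start: int  # index of the first point
    stop: int  # index of the last point (inclusive)
    duration: float  # s
    center: tuple[float, float]
    boundary: Ellipse | None
    lam: float  # spring constant, s⁻¹ (mean of axes; NaN if not estimable)
    D: float  # μm²/s (NaN if not estimable)


def detect_confinements(
    ens: TrajectoryEnsemble, n_nh: int = 10, r_nh: float = 0.3
) -> list[ConfinementEvent]:
    """Detect transient confinement periods along each trajectory.

    From each candidate start, the successor window grows while every
    member point stays within ``r_nh`` of the running center of mass;
    windows of at least ``n_nh`` successors are recorded as confinement
    events.  Overlapping candidates collapse to the earliest-start maximal
    event (scanning resumes after the event end).  Each event gets a 95%
    confidence ellipse and per-axis OU parameters with the event center of
    mass as the OU center.
    """
    if n_nh < 3:
        raise ValueError("n_nh must be >= 3")
    if r_nh <= 0:
        raise ValueError("r_nh must be positive")
    events: list[ConfinementEvent] = []
    for tr in ens.trajectories:
        M = len(tr)
        j = 0
        while j + n_nh < M:
            span = _grow_window(tr.xy, j, n_nh, r_nh)
            if span is None:
                j += 1
                continue
            stop = span
            xy = tr.xy[j : stop + 1]
            com = xy.mean(axis=0)
            try:
                ell = confidence_ellipse(xy, 95.0)
            except ValueError:
                ell = None
            fit = ou_mle(xy[:-1], xy[1:], ens.dt, mu=(com[0], com[1]))
            lam = float(np.mean(fit.lam)) if fit.valid else np.nan
            D = fit.D if fit.valid else np.nan
            events.append(
                ConfinementEvent(
                    tr.id,
                    j,
                    stop,
                    float(tr.t[stop] - tr.t[j]),
                    (float(com[0]), float(com[1])),
                    ell,
                    lam,
                    D,
                )
            )
            j = stop + 1
        # per-trajectory bookkeeping is derived downstream
    return events


def _grow_window(xy: np.ndarray, j: int, n_nh: int, r_nh: float) -> int | None:
    """Largest stop index of a confined window starting at j, or None."""
    M = xy.shape[0]
    stop = j + n_nh
    if stop >= M:
        return None
    window = xy[j : stop + 1]
    com = window.mean(axis=0)
    if _max_dist(window, com) >= r_nh:
        return None
    while stop + 1 < M:
        cand = xy[j : stop + 2]
        com = cand.mean(axis=0)
        if np.hypot(*(xy[stop + 1] - com)) >= r_nh or _max_dist(cand, com) >= r_nh:
            break
        stop += 1
    return stop


def _max_dist(pts: np.ndarray, com: np.ndarray) -> float:
    return float(np.max(np.hypot(pts[:, 0] - com[0], pts[:, 1] - com[1])))


def confined_fraction(ens: TrajectoryEnsemble, events: list[ConfinementEvent]) -> dict:
    """Per-trajectory confined-time fraction and event count."""
    total = {tr.id: (len(tr) - 1) * ens.dt for tr in ens.trajectories}
    frac = {tid: 0.0 for tid in total}
    count = {tid: 0 for tid in total}
    for ev in events:
        frac[ev.traj_id] += ev.duration
        count[ev.traj_id] += 1
    for tid in frac:
        frac[tid] = frac[tid] / total[tid] if total[tid] > 0 else 0.0
    return {"fraction": frac, "count": count}


def fit_exponential_durations(durations: np.ndarray, t_min: float = 0.0) -> float:
    """ML time constant of (left-truncated) exponential durations.

    For an exponential distribution observed only above ``t_min``, the MLE
    of the time constant is mean(d) − t_min (memorylessness).
    """
    d = np.asarray(durations, dtype=float)
    d = d[d >= t_min]
    if d.size == 0:
        raise ValueError("no durations above the truncation threshold")
    return float(d.mean() - t_min)
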