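"""Potential-well representation, estimators, and detection algorithms.

A high-density nanodomain is modeled as a truncated elliptic parabolic
potential U(X) = A[(x'/a)² + (y'/b)² − 1] inside an elliptic boundary and 0
outside.  Inside the boundary the motion is an Ornstein-Uhlenbeck (OU)
process with per-axis spring constants λ⁽¹⁾ = 2A/a², λ⁽²⁾ = 2A/b² and
diffusion coefficient D; the well energy is E = A/D in kT and the mean
residence time follows a Kramers-type escape formula.

Three detection algorithms are provided, all seeded at the highest-density
bins of a coarse grid:

* hybrid density-drift: grow square neighbourhoods, fit the confidence
  ellipse and the OU likelihood, stop at the first local maximum of the
  per-ring likelihood (optionally across several grid scales);
* density-based: level-set refined center, annulus scan of the
  ellipticity-corrected radial density, stop where the density stops
  decreasing;
* drift-based: least-squares projection of the local drift map onto a
  parabolic field, stop at the minimum of the parabolic index S ∈ [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2

from .maps import Grid, density_map
from .traj_core import TrajectoryEnsemble

__all__ = [
    "Ellipse",
    "OUFit",
    "PotentialWell",
    "HybridParams",
    "DensityParams",
    "DriftParams",
    "confidence_ellipse",
    "chi2_quantile",
    "ou_mle",
    "ou_mle_1d",
    "ou_loglik_1d",
    "brownian_loglik_1d",
    "moment_lambda",
    "residence_time",
    "parabolic_index",
    "detect_wells_hybrid",
    "detect_wells_density",
    "detect_wells_drift",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Ellipse:
    """Ellipse with center μ, semi-axes a ≥ b > 0 and orientation φ.

    φ is the angle of the major axis with the x-axis, normalized to
    (−π/2, π/2].
    """

    center: tuple[float, float]
    a: float
    b: float
    phi: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("need a >= b > 0")
        phi = float(self.phi)
        phi = (phi + np.pi / 2) % np.pi - np.pi / 2
        if phi == -np.pi / 2:
            phi = np.pi / 2
        object.__setattr__(self, "phi", phi)

    def to_frame(self, xy: np.ndarray) -> np.ndarray:
        """Coordinates relative to the center, rotated into the axes frame."""
        c, s = np.cos(self.phi), np.sin(self.phi)
        rel = np.atleast_2d(xy) - np.asarray(self.center)
        return rel @ np.array([[c, -s], [s, c]])

    def contains(self, xy: np.ndarray) -> np.ndarray:
        loc = self.to_frame(xy)
        return (loc[:, 0] / self.a) ** 2 + (loc[:, 1] / self.b) ** 2 <= 1.0

    def polygon(self, n: int = 64):
        """Shapely polygon approximation with n vertices."""
        from shapely.geometry import Polygon

        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        c, s = np.cos(self.phi), np.sin(self.phi)
        x = self.a * np.cos(th)
        y = self.b * np.sin(th)
        pts = np.column_stack([x * c - y * s, x * s + y * c]) + np.asarray(self.center)
        return Polygon(pts)

    def overlaps(self, other: "Ellipse") -> bool:
        d = np.hypot(
            self.center[0] - other.center[0], self.center[1] - other.center[1]
        )
        if d > self.a + other.a:
            return False
        return self.polygon().intersects(other.polygon())

    @property
    def area(self) -> float:
        return float(np.pi * self.a * self.b)


def chi2_quantile(conf: float) -> float:
    """ψ scale factor of a confidence ellipse: χ² quantile with 2 df.

    conf is a percentage; e.g. ψ₉₅ = 5.991, ψ₉₉ = 9.210, ψ₉₀ = 4.605.
    """
    if not 0 < conf < 100:
        raise ValueError("conf is a percentage in (0, 100)")
    return float(chi2.ppf(conf / 100.0, df=2))


def confidence_ellipse(points: np.ndarray, conf: float = 95.0) -> Ellipse:
    """Confidence ellipse of a 2-D point cloud.

    The center is the sample mean, the axes come from the eigendecomposition
    of the sample covariance (ddof=1), scaled by √ψ with ψ the chi-squared
    (2 df) quantile at the requested confidence level.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    mu = pts.mean(axis=0)
    cov = np.cov(pts.T, ddof=1)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0:
        raise ValueError("degenerate covariance")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    psi = chi2_quantile(conf)
    a = float(np.sqrt(psi * evals[1]))
    b = float(np.sqrt(psi * evals[0]))
    u = evecs[:, 1]  # major axis direction
    phi = float(np.arctan2(u[1], u[0]))
    return Ellipse((float(mu[0]), float(mu[1])), a, b, phi)


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck maximum likelihood


@dataclass
class OUFit:
    """Per-axis OU maximum-likelihood fit of successive position pairs."""

    lam: tuple[float, float]  # spring constants per axis, s⁻¹
    D: float  # diffusion coefficient, μm²/s (mean of axes)
    D_axes: tuple[float, float]
    logL: float
    mu: tuple[float, float]
    n: int
    valid: bool


def ou_mle_1d(
    x0: np.ndarray, x1: np.ndarray, dt: float, mu: float | None = None
) -> tuple[float, float, float, float, bool]:
    """1-D OU MLE from successive pairs (x0[i], x1[i]) separated by dt.

    The discrete transition is x1 | x0 ~ N(μ + (x0 − μ)e^{−λΔt}, s) with
    s = D(1 − e^{−2λΔt})/λ.  The regression slope of x1 on x0 gives
    e^{−λ̂Δt}; the residual variance then gives D̂.  When ``mu`` is None it
    is profiled out (regression intercept); otherwise the supplied center
    is used in the conditional mean.

    Returns (λ̂, D̂, logL, μ̂, valid); valid is False when the slope is
    non-positive (anti-persistent sample) or degenerate.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    n = x0.size
    if n < 2:
        return np.nan, np.nan, np.nan, np.nan, False
    m0, m1 = x0.mean(), x1.mean()
    var0 = np.mean((x0 - m0) ** 2)
    if var0 <= 0:
        return np.nan, np.nan, np.nan, m0 if mu is None else mu, False
    theta = float(np.mean((x0 - m0) * (x1 - m1)) / var0)
    if theta <= 0:
        return np.nan, np.nan, np.nan, m0 if mu is None else mu, False
    lam = -np.log(theta) / dt
    if mu is None:
        mu_hat = (m1 - theta * m0) / (1.0 - theta) if abs(1.0 - theta) > 1e-12 else m0
    else:
        mu_hat = float(mu)
    resid = x1 - (mu_hat + (x0 - mu_hat) * theta)
    s_hat = float(np.mean(resid**2))
    if s_hat <= 0:
        return lam, np.nan, np.nan, mu_hat, False
    # D = λ s / (1 − e^{−2λΔt}); λ→0 limit s/(2Δt)
    denom = -np.expm1(-2.0 * lam * dt)
    D = s_hat * (lam / denom if abs(lam) > 1e-12 else 1.0 / (2.0 * dt))
    logL = -0.5 * n * (np.log(2.0 * np.pi * s_hat) + 1.0)
    return float(lam), float(D), float(logL), float(mu_hat), True


def ou_loglik_1d(
    x0: np.ndarray, x1: np.ndarray, dt: float, mu: float, lam: float, D: float
) -> float:
    """Exact discrete OU transition log-likelihood at given parameters.

    Valid for any real λ (λ < 0 is a repulsive linear drift); the λ → 0
    limit is pure Brownian motion with s = 2DΔt.
    """
    if abs(lam) > 1e-12:
        theta = np.exp(-lam * dt)
        s = D * -np.expm1(-2.0 * lam * dt) / lam
    else:
        theta = 1.0
        s = 2.0 * D * dt
    if s <= 0:
        return -np.inf
    resid = x1 - (mu + (x0 - mu) * theta)
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * s) + resid**2 / s))


def brownian_loglik_1d(x0: np.ndarray, x1: np.ndarray, dt: float) -> float:
    """Profile log-likelihood of the pure-Brownian (λ = 0) null model."""
    s = float(np.mean((x1 - x0) ** 2))
    if s <= 0:
        return np.inf
    return float(-0.5 * x0.size * (np.log(2.0 * np.pi * s) + 1.0))


def _rotate(xy: np.ndarray, phi: float) -> np.ndarray:
    """Rotate row vectors by phi (counter-clockwise)."""
    c, s = np.cos(phi), np.sin(phi)
    return np.atleast_2d(xy) @ np.array([[c, s], [-s, c]])


def ou_mle(
    p0: np.ndarray,
    p1: np.ndarray,
    dt: float,
    mu: tuple[float, float] | None = None,
    phi: float = 0.0,
) -> OUFit:
    """2-D OU MLE: independent per-axis fits in the frame rotated by φ.

    ``p0`` and ``p1`` are (n, 2) successive position pairs.  The reported D
    is the mean of the per-axis diffusion estimates and logL the sum of the
    axis log-likelihoods.
    """
    q0 = _rotate(p0, -phi)
    q1 = _rotate(p1, -phi)
    mu_r = None if mu is None else tuple(_rotate(np.asarray(mu), -phi)[0])
    lams, Ds, Ls, mus, ok = [], [], [], [], True
    for ax in range(2):
        lam, D, L, m, valid = ou_mle_1d(
            q0[:, ax], q1[:, ax], dt, None if mu_r is None else mu_r[ax]
        )
        lams.append(lam)
        Ds.append(D)
        Ls.append(L)
        mus.append(m)
        ok = ok and valid
    mu_out = tuple(_rotate(np.asarray(mus), phi)[0])
    return OUFit(
        (lams[0], lams[1]),
        float(np.mean(Ds)) if ok else np.nan,
        (Ds[0], Ds[1]),
        float(np.sum(Ls)) if ok else np.nan,
        mu_out,
        p0.shape[0],
        ok,
    )


def moment_lambda(
    p0: np.ndarray, p1: np.ndarray, dt: float, mu: tuple[float, float], phi: float = 0.0
) -> tuple[float, float]:
    """Moment-based spring constants λ = D̂/Var per axis.

    Uses the free-diffusion second-moment estimator D̂ = ⟨‖ΔX‖²⟩/(4Δt) and
    the empirical positional variance about the supplied center.  Simpler
    than the MLE but biased low under confinement, since the mean squared
    displacement saturates at finite Δt.
    """
    q0 = _rotate(p0, -phi)
    q1 = _rotate(p1, -phi)
    mu_r = _rotate(np.asarray(mu), -phi)[0]
    D_msd = float(np.mean(np.sum((q1 - q0) ** 2, axis=1)) / (4.0 * dt))
    out = []
    for ax in range(2):
        var = float(np.mean((q0[:, ax] - mu_r[ax]) ** 2))
        out.append(D_msd / var if var > 0 else np.nan)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# well object


def residence_time(a: float, b: float, A: float, D: float) -> float | None:
    """Kramers-type mean residence time τe = D r²/(4A²) · e^{A/D}.

    r = √(ab) is the harmonic-mean radius of the boundary ellipse; the
    formula assumes a ≈ b.  Undefined (None) for A = 0.
    """
    if A <= 0:
        return None
    r2 = a * b
    return float(D * r2 / (4.0 * A**2) * np.exp(A / D))


@dataclass
class PotentialWell:
    """A detected potential well and its parameterization."""

    boundary: Ellipse
    A: float  # attraction coefficient, μm²/s
    D: float  # diffusion coefficient, μm²/s
    score: float  # ring log-likelihood (hybrid/density) or parabolic index (drift)
    algorithm: str
    scale: float  # grid size Δx used, μm
    logL: float = np.nan  # in-ellipse OU log-likelihood (for cross-scale ranking)
    llr: float = np.nan  # OU-vs-Brownian log-likelihood ratio inside the boundary
    n_pairs: int = 0  # displacement pairs inside the boundary

    @property
    def llr_per_pair(self) -> float:
        return self.llr / self.n_pairs if self.n_pairs else np.nan

    @property
    def energy(self) -> float:
        """E = A/D in kT."""
        return self.A / self.D

    @property
    def tau_e(self) -> float | None:
        return residence_time(self.boundary.a, self.boundary.b, self.A, self.D)

    @property
    def center(self) -> tuple[float, float]:
        return self.boundary.center


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class HybridParams:
    """Hybrid density-drift detection parameters (all lengths in μm)."""

    d_pct: float = 1.0  # seed bins: top d% of populated-bin densities
    dx: float = 0.08  # grid size (fixed-scale variant)
    dx_grid: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)  # multiscale Δx values
    max_size: float = 1.0  # Ms: maximum region size
    ell_perc: float = 95.0  # ellPerc: confidence level of the boundary
    ring_min_pts: int = 10  # ringMinPts: min trajectories per ring
    e_max: float = 10.0  # wells with E > e_max are filtered out
    llr_min: float = 13.0  # OU-vs-Brownian log-likelihood ratio screen
    density_frac: float = 0.6  # keep neighbourhoods within this fraction of peak evidence density
    b_min: float = 0.04  # degenerate wells (b below this) rejected
    min_pts: int = 30  # minimum points in a neighbourhood to attempt a fit


@dataclass(frozen=True)
class DensityParams:
    """Density-based detection parameters (lengths in μm)."""

    d_pct: float = 1.0
    dx: float = 0.08  # seed grid size
    alphas: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    loc_grid_dx: float = 0.02  # locGridDx: refined local grid bin
    dr: float = 0.02  # annulus width Δr
    r_min: float = 0.06
    r_max: float = 0.5
    rat_max_dist: float = 0.3  # ratMaxDist: max radius for the axis-ratio scan
    ell_perc: float = 95.0
    e_max: float = 10.0
    llr_min: float = 20.0
    b_min: float = 0.04
    min_pts: int = 30


@dataclass(frozen=True)
class DriftParams:
    """Drift-based detection parameters (lengths in μm)."""

    d_pct: float = 1.0
    dx: float = 0.08
    w_max: float = 1.0  # maximum region size
    ell_perc: float = 95.0
    min_disp_bin: int = 5  # displacements per local drift bin
    s_max: float = 0.8  # maximum accepted parabolic index
    e_max: float = 10.0
    b_min: float = 0.04
    min_pts: int = 30


# ---------------------------------------------------------------------------
# seeding


def _seed_centers(ens: TrajectoryEnsemble, dx: float, d_pct: float) -> np.ndarray:
    """Centers of the top-d% density bins, collapsed to local maxima.

    Adjacent (8-connected) seed bins would all start the same search, so
    each connected component keeps only its densest bin.
    """
    dm = density_map(ens, dx)
    vals = dm.values
    if not np.any(dm.counts > 0):
        return np.empty((0, 2))
    thresh = max(np.percentile(vals, 100.0 - d_pct), np.finfo(float).tiny)
    mask = (vals >= thresh) & (dm.counts > 0)
    from scipy.ndimage import label

    lab, nlab = label(mask, structure=np.ones((3, 3), dtype=int))
    cx, cy = dm.grid.centers()
    seeds = []
    for comp in range(1, nlab + 1):
        ii, jj = np.nonzero(lab == comp)
        best = np.argmax(vals[ii, jj])
        seeds.append((cx[ii[best]], cy[jj[best]]))
    return np.asarray(seeds)


def _dedup(wells: list[PotentialWell]) -> list[PotentialWell]:
    """Keep the best-scoring well among overlapping detections.

    Ranking uses the in-ellipse log-likelihood when available (comparable
    across grid scales), falling back to the algorithm score.
    """
    def rank(w: PotentialWell) -> float:
        if np.isfinite(w.logL):
            return w.logL
        # drift scores are parabolic indices: lower is better
        return -w.score if w.algorithm == "drift" else w.score

    kept: list[PotentialWell] = []
    for w in sorted(wells, key=rank, reverse=True):
        if not any(w.boundary.overlaps(k.boundary) for k in kept):
            kept.append(w)
    return kept


# ---------------------------------------------------------------------------
# hybrid density-drift algorithm


def _pairs(ens: TrajectoryEnsemble):
    disp = ens.displacements()
    return disp.origins, disp.origins + disp.dxy, disp.traj_index


def detect_wells_hybrid(
    ens: TrajectoryEnsemble, p: HybridParams = HybridParams(), multiscale: bool = False
) -> list[PotentialWell]:
    """Hybrid density-drift potential-well detection.

    Seeds at the densest bins of a Δx grid; around each seed, square
    neighbourhoods of side (2k+1)Δx are grown (re-centered each iteration
    at the enclosed center of mass), the ellPerc confidence ellipse ε_k is
    fitted and OU parameters estimated from the pairs inside ε_k.  The
    retained iteration is the first local maximum of the OU log-likelihood
    of the pairs in the ring ε_k ∖ ε_{k−1}.  With ``multiscale=True`` the
    procedure is repeated over ``p.dx_grid`` and overlapping detections
    keep the scale with the highest in-ellipse likelihood.

    Detections are screened: positive spring constants on both axes, an
    OU-vs-Brownian log-likelihood ratio of at least ``llr_min``, energy in
    (0, e_max], and a non-degenerate minor axis.
    """
    scales = p.dx_grid if multiscale else (p.dx,)
    candidates: list[PotentialWell] = []
    for dx in scales:
        candidates.extend(_hybrid_fixed_scale(ens, replace(p, dx=dx)))
    return _dedup(candidates)


def _hybrid_fixed_scale(ens: TrajectoryEnsemble, p: HybridParams) -> list[PotentialWell]:
    seeds = _seed_centers(ens, p.dx, p.d_pct)
    if seeds.size == 0:
        return []
    pts = ens.points()
    p0, p1, ti = _pairs(ens)
    K = int(np.ceil(p.max_size / p.dx))
    out: list[PotentialWell] = []
    for seed in seeds:
        w = _hybrid_one_seed(ens, pts, p0, p1, ti, seed, K, p)
        if w is not None:
            out.append(w)
    return out


def _hybrid_one_seed(ens, pts, p0, p1, ti, seed, K, p: HybridParams):
    mu = np.asarray(seed, dtype=float)
    iters = []  # (k, ellipse, fit, A)
    for k in range(1, K + 1):
        half = (2 * k + 1) * p.dx / 2.0
        sel = np.all(np.abs(pts - mu) <= half, axis=1)
        if sel.sum() < p.min_pts:
            continue
        mu = pts[sel].mean(axis=0)
        try:
            ell = confidence_ellipse(pts[sel], p.ell_perc)
        except ValueError:
            continue
        ell = Ellipse((mu[0], mu[1]), ell.a, ell.b, ell.phi)
        inside = ell.contains(p0)
        if inside.sum() < p.min_pts:
            continue
        fit = ou_mle(p0[inside], p1[inside], ens.dt, mu=tuple(mu), phi=ell.phi)
        if not fit.valid:
            iters.append((k, ell, None, np.nan))
            continue
        A = 0.5 * float(np.mean([fit.lam[0] * ell.a**2, fit.lam[1] * ell.b**2]))
        iters.append((k, ell, fit, A))

    # ring likelihoods L_k for k >= 2 (ring between consecutive evaluated ellipses)
    ring: list[tuple[int, float]] = []  # (index into iters, L)
    for idx in range(1, len(iters)):
        k, ell, fit, A = iters[idx]
        _, prev_ell, _, _ = iters[idx - 1]
        if fit is None:
            continue
        in_cur = ell.contains(p0)
        in_prev = prev_ell.contains(p0)
        sel = in_cur & ~in_prev
        if np.unique(ti[sel]).size < p.ring_min_pts:
            continue
        q0 = _rotate(p0[sel] - np.asarray(ell.center), -ell.phi)
        q1 = _rotate(p1[sel] - np.asarray(ell.center), -ell.phi)
        if min(fit.lam) <= 0 or fit.D <= 0:
            continue
        L = ou_loglik_1d(q0[:, 0], q1[:, 0], ens.dt, 0.0, fit.lam[0], fit.D) + ou_loglik_1d(
            q0[:, 1], q1[:, 1], ens.dt, 0.0, fit.lam[1], fit.D
        )
        # per-pair normalization keeps the score comparable across rings of
        # very different occupancy (the raw sum grows with ring population)
        ring.append((idx, L / q0.shape[0]))
    if not ring:
        return None
    # first local maximum: first point where the curve stops increasing
    sel_idx, best_L = ring[-1]
    for r in range(len(ring) - 1):
        if ring[r][1] >= ring[r + 1][1]:
            sel_idx, best_L = ring[r]
            if r == 0:
                logger.debug("ring likelihood monotone decreasing at seed %s", seed)
            break
    # the selected iteration can overshoot into the background for shallow
    # wells (the ring curve keeps creeping up once rings are Brownian), so
    # among the iterations up to the ring optimum keep the one with the
    # highest OU-evidence density (log-likelihood ratio per pair), which
    # peaks when the ellipse matches the actual basin
    ring_L = dict(ring)
    passing: list[PotentialWell] = []
    for idx in range(sel_idx, -1, -1):
        k, ell, fit, A = iters[idx]
        if fit is None:
            continue
        score = ring_L.get(idx, best_L)
        w = _screen_candidate(ens, p0, p1, ell, fit, A, score, "hybrid", p.dx, p)
        if w is not None:
            passing.append(w)
    if not passing:
        return None
    top = max(w.llr_per_pair for w in passing)
    near_top = [w for w in passing if w.llr_per_pair >= p.density_frac * top]
    return max(near_top, key=lambda w: w.n_pairs)


def _screen_candidate(ens, p0, p1, ell, fit, A, score, algo, dx, p) -> PotentialWell | None:
    """Shared validity screen: OU evidence, energy band, non-degeneracy.

    Wells whose boundary leaves the observed region are rejected: a basin
    cut by the field of view cannot be parameterized, and reflection or
    loss at the border mimics mean reversion.
    """
    if fit is None or not fit.valid or min(fit.lam) <= 0 or not np.isfinite(A) or A <= 0:
        return None
    if fit.D <= 0 or ell.b < p.b_min:
        return None
    xmin, ymin, xmax, ymax = ens.bbox
    c, s = np.cos(ell.phi), np.sin(ell.phi)
    ex = np.hypot(ell.a * c, ell.b * s)
    ey = np.hypot(ell.a * s, ell.b * c)
    if (
        ell.center[0] - ex < xmin
        or ell.center[0] + ex > xmax
        or ell.center[1] - ey < ymin
        or ell.center[1] + ey > ymax
    ):
        return None
    E = A / fit.D
    if not (0 < E <= p.e_max):
        return None
    inside = ell.contains(p0)
    q0 = _rotate(p0[inside] - np.asarray(ell.center), -ell.phi)
    q1 = _rotate(p1[inside] - np.asarray(ell.center), -ell.phi)
    logL = 0.0
    llr = 0.0
    for ax in range(2):
        l_ou = ou_loglik_1d(q0[:, ax], q1[:, ax], ens.dt, 0.0, fit.lam[ax], fit.D_axes[ax])
        llr += l_ou - brownian_loglik_1d(q0[:, ax], q1[:, ax], ens.dt)
        logL += l_ou
    llr_min = getattr(p, "llr_min", None)
    if llr_min is not None and llr < llr_min:
        return None
    return PotentialWell(
        ell, float(A), float(fit.D), float(score), algo, dx,
        logL=logL, llr=float(llr), n_pairs=int(inside.sum()),
    )


# ---------------------------------------------------------------------------
# density-based algorithm


def detect_wells_density(
    ens: TrajectoryEnsemble, p: DensityParams = DensityParams()
) -> list[PotentialWell]:
    """Density-based potential-well detection.

    For each seed, the center is refined as the mean over the α grid of
    level-set centers on a fine local density map.  Concentric annuli of
    width Δr are scanned: the axis ratio κ of the annulus confidence
    ellipses (for r < ratMaxDist) defines an ellipticity-corrected radial
    distance, and the boundary radius is the first annulus where the
    corrected radial density stops decreasing.  D comes from the OU MLE
    inside the boundary and A from the stationary covariance relation.
    """
    seeds = _seed_centers(ens, p.dx, p.d_pct)
    if seeds.size == 0:
        return []
    pts = ens.points()
    p0, p1, _ = _pairs(ens)
    out = []
    for seed in seeds:
        w = _density_one_seed(ens, pts, p0, p1, seed, p)
        if w is not None:
            out.append(w)
    return _dedup(out)


def _local_density_grid(pts: np.ndarray, center: np.ndarray, half: float, dx: float):
    """Counts on a local grid of half-extent ``half`` centered at ``center``."""
    n = int(np.ceil(2 * half / dx))
    origin = center - n * dx / 2.0
    grid = Grid((origin[0], origin[1]), dx, n, n)
    i, j, valid = grid.bin_index(pts)
    counts = np.zeros((n, n))
    np.add.at(counts, (i[valid], j[valid]), 1)
    return grid, counts


def _density_one_seed(ens, pts, p0, p1, seed, p: DensityParams):
    grid, counts = _local_density_grid(pts, np.asarray(seed, float), p.r_max, p.loc_grid_dx)
    m_star = counts.max()
    if m_star <= 0:
        return None
    cx, cy = grid.centers()
    i, j, valid = grid.bin_index(pts)
    binval = np.zeros(pts.shape[0])
    binval[valid] = counts[i[valid], j[valid]]
    centers_alpha = []
    for alpha in p.alphas:
        member = binval > alpha * m_star
        if member.sum() >= 3:
            centers_alpha.append(pts[member].mean(axis=0))
    if not centers_alpha:
        return None
    mu0 = np.mean(centers_alpha, axis=0)

    rel = pts - mu0
    r_euc = np.hypot(rel[:, 0], rel[:, 1])
    radii = np.arange(p.r_min, p.r_max + 1e-9, p.dr)
    kappa, phi_star = 1.0, 0.0
    best_cv = -np.inf
    for rk in radii:
        if rk >= p.rat_max_dist:
            break
        ann = (r_euc >= rk - p.dr) & (r_euc < rk)
        if ann.sum() < 10:
            continue
        try:
            ell = confidence_ellipse(pts[ann], p.ell_perc)
        except ValueError:
            continue
        cv = ell.a / ell.b
        if cv > best_cv:
            best_cv, kappa, phi_star = cv, cv, ell.phi

    loc = _rotate(rel, -phi_star)
    re = np.hypot(loc[:, 0], kappa * loc[:, 1])
    dens = np.full(radii.size, np.nan)
    for idx, rk in enumerate(radii):
        cnt = np.count_nonzero((re >= rk - p.dr) & (re < rk))
        area = np.pi * (rk**2 - (rk - p.dr) ** 2) / kappa
        dens[idx] = cnt / area
    k_star = None
    for idx in range(1, radii.size):
        if np.isfinite(dens[idx - 1]) and np.isfinite(dens[idx]) and dens[idx] > dens[idx - 1]:
            k_star = idx
            break
    if k_star is None:
        return None
    a_star = float(radii[k_star])
    b_star = a_star / kappa
    try:
        ell = Ellipse((float(mu0[0]), float(mu0[1])), a_star, b_star, phi_star)
    except ValueError:
        return None
    inside = ell.contains(p0)
    if inside.sum() < p.min_pts:
        return None
    fit = ou_mle(p0[inside], p1[inside], ens.dt, mu=tuple(mu0), phi=phi_star)
    if not fit.valid or fit.D <= 0:
        return None
    in_pts = ell.contains(pts)
    loc_pts = _rotate(pts[in_pts] - mu0, -phi_star)
    s11 = float(np.mean(loc_pts[:, 0] ** 2))
    s22 = float(np.mean(loc_pts[:, 1] ** 2))
    if s11 <= 0 or s22 <= 0:
        return None
    A = fit.D / 2.0 * (a_star**2 / s11 + b_star**2 / s22) / 2.0
    return _screen_candidate(
        ens, p0, p1, ell, fit, A, float(dens[k_star]), "density", p.dx, p
    )


# ---------------------------------------------------------------------------
# drift-based algorithm


def parabolic_index(
    bin_xy: np.ndarray, drift: np.ndarray, a: float, b: float
) -> tuple[float, float]:
    """(A, S): least-squares parabolic fit of a drift field and its index.

    ``bin_xy`` are bin centers relative to the well center in the ellipse
    frame; ``drift`` the corresponding drift vectors in the same frame.
    The parabolic template is a(X) = −2A(x₁/a², x₂/b²); S ∈ [0, 1] is the
    residual fraction: 0 for a perfect parabolic field, ≈1 for random
    drift.
    """
    x1, x2 = bin_xy[:, 0], bin_xy[:, 1]
    num = float(np.sum(drift[:, 0] * x1 / a**2 + drift[:, 1] * x2 / b**2))
    den = float(np.sum(x1**2 / a**4 + x2**2 / b**4))
    pw = float(np.sum(drift**2))
    if den <= 0 or pw <= 0:
        return np.nan, np.nan
    A = -num / (2.0 * den)
    S = 1.0 - num**2 / (den * pw)
    return A, float(np.clip(S, 0.0, 1.0))


def detect_wells_drift(
    ens: TrajectoryEnsemble, p: DriftParams = DriftParams()
) -> list[PotentialWell]:
    """Drift-based potential-well detection.

    Square neighbourhoods grow as in the hybrid algorithm; at each
    iteration a local drift map on a grid centered at the current center is
    projected onto the parabolic field template, yielding an attraction
    coefficient A_k (least squares) and the parabolic index S_k ∈ [0, 1].
    The iteration minimizing S_k is retained; D is the local mean-squared
    displacement estimator inside the final ellipse.
    """
    seeds = _seed_centers(ens, p.dx, p.d_pct)
    if seeds.size == 0:
        return []
    pts = ens.points()
    disp = ens.displacements()
    p0 = disp.origins
    dxy = disp.dxy
    K = max(1, int(np.floor(p.w_max / p.dx)))
    out = []
    for seed in seeds:
        w = _drift_one_seed(ens, pts, p0, dxy, seed, K, p)
        if w is not None:
            out.append(w)
    return _dedup(out)


def _drift_one_seed(ens, pts, p0, dxy, seed, K, p: DriftParams):
    mu = np.asarray(seed, dtype=float)
    best = None  # (S, ell, A)
    for k in range(1, K + 1):
        half = (2 * k + 1) * p.dx / 2.0
        sel = np.all(np.abs(pts - mu) <= half, axis=1)
        if sel.sum() < p.min_pts:
            continue
        mu = pts[sel].mean(axis=0)
        try:
            ell = confidence_ellipse(pts[sel], p.ell_perc)
        except ValueError:
            continue
        ell = Ellipse((mu[0], mu[1]), ell.a, ell.b, ell.phi)
        # local drift map on a grid centered at mu (mu at the center of a bin)
        nbin = 2 * k + 1
        origin = mu - (nbin / 2.0) * p.dx
        grid = Grid((origin[0], origin[1]), p.dx, nbin, nbin)
        gi, gj, gvalid = grid.bin_index(p0)
        flat = gi[gvalid] * nbin + gj[gvalid]
        nb = nbin * nbin
        cnt = np.bincount(flat, minlength=nb)
        sx = np.bincount(flat, weights=dxy[gvalid, 0], minlength=nb)
        sy = np.bincount(flat, weights=dxy[gvalid, 1], minlength=nb)
        good = cnt >= p.min_disp_bin
        if good.sum() < 3:
            continue
        with np.errstate(invalid="ignore"):
            av = np.column_stack([sx, sy]) / cnt[:, None] / ens.dt
        cxs, cys = grid.centers()
        ii, jj = np.unravel_index(np.nonzero(good)[0], (nbin, nbin))
        bc = np.column_stack([cxs[ii], cys[jj]])
        in_ell = ell.contains(bc)
        if in_ell.sum() < 3:
            continue
        bc_loc = _rotate(bc[in_ell] - mu, -ell.phi)
        av_loc = _rotate(av[good][in_ell], -ell.phi)
        A, S = parabolic_index(bc_loc, av_loc, ell.a, ell.b)
        if not np.isfinite(S):
            continue
        if best is None or S < best[0]:
            best = (S, ell, A)
    if best is None:
        return None
    S, ell, A = best
    if A <= 0 or S > p.s_max or ell.b < p.b_min:
        return None
    inside = ell.contains(p0)
    if inside.sum() < p.min_pts:
        return None
    D = float(np.mean(np.sum(dxy[inside] ** 2, axis=1)) / (4.0 * ens.dt))
    if D <= 0:
        return None
    E = A / D
    if not (0 < E <= p.e_max):
        return None
    return PotentialWell(ell, float(A), D, float(S), "drift", p.dx)
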