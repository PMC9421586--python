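"""Grid-discretized density, drift, and diffusion estimation.

Trajectory points are binned on a lattice of square half-open bins
[x, x+Δx) × [y, y+Δx).  Per-bin estimators:

* density: ρ(x_k) = N_k / Δx², optionally smoothed with a small d×d
  Gaussian kernel (d ∈ {1, 3, 5});
* drift: a(x_k) = mean of ΔX/Δt over displacements originating in the bin;
* diffusion tensor: D^(u,v)(x_k) = mean of ΔX_u ΔX_v / (2Δt).

Bins with fewer samples than a minimum count are masked as missing (NaN),
never reported as 0.  The cosine-filtered variants replace the square bin
by a disk of radius r around each (refined) bin center and weight each
displacement by cos(π/2 · d/r) of its origin's distance d, which increases
coverage and reduces the error of the maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve
from sklearn.neighbors import KDTree

from .traj_core import TrajectoryEnsemble

__all__ = [
    "Grid",
    "ScalarMap",
    "VectorMap",
    "density_map",
    "drift_map",
    "diffusion_map",
    "cosine_filtered_maps",
]


@dataclass(frozen=True)
class Grid:
    """Square-bin lattice anchored at ``origin`` (the bbox lower corner)."""

    origin: tuple[float, float]  # μm
    dx: float  # bin width, μm
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.nx < 1 or self.ny < 1:
            raise ValueError("invalid grid")

    @classmethod
    def for_ensemble(cls, ens: TrajectoryEnsemble, dx: float) -> "Grid":
        xmin, ymin, xmax, ymax = ens.bbox
        nx = max(1, int(np.floor((xmax - xmin) / dx)) + 1)
        ny = max(1, int(np.floor((ymax - ymin) / dx)) + 1)
        return cls((xmin, ymin), dx, nx, ny)

    def bin_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, valid) bin indices of points; half-open bin convention."""
        rel = (np.atleast_2d(xy) - np.asarray(self.origin)) / self.dx
        i = np.floor(rel[:, 0]).astype(np.intp)
        j = np.floor(rel[:, 1]).astype(np.intp)
        valid = (i >= 0) & (i < self.nx) & (j >= 0) & (j < self.ny)
        return i, j, valid

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of bin-center coordinates along x and y."""
        x0, y0 = self.origin
        return (
            x0 + (np.arange(self.nx) + 0.5) * self.dx,
            y0 + (np.arange(self.ny) + 0.5) * self.dx,
        )


@dataclass
class ScalarMap:
    """Per-bin scalar field with sample counts; missing bins are NaN."""

    grid: Grid
    values: np.ndarray  # (nx, ny)
    counts: np.ndarray  # (nx, ny) int

    def to_dataframe(self):
        import pandas as pd

        cx, cy = self.grid.centers()
        ii, jj = np.meshgrid(np.arange(self.grid.nx), np.arange(self.grid.ny), indexing="ij")
        return pd.DataFrame(
            {
                "i": ii.ravel(),
                "j": jj.ravel(),
                "x": cx[ii.ravel()],
                "y": cy[jj.ravel()],
                "value": self.values.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass
class VectorMap:
    """Per-bin 2-vector field (μm/s) with sample counts; missing bins NaN."""

    grid: Grid
    vectors: np.ndarray  # (nx, ny, 2)
    counts: np.ndarray  # (nx, ny) int


def _gaussian_kernel(d: int) -> np.ndarray:
    """d×d Gaussian kernel, σ = d/3 bins, renormalized to unit sum."""
    if d % 2 != 1 or d < 1:
        raise ValueError("kernel size must be an odd positive integer")
    if d == 1:
        return np.ones((1, 1))
    ax = np.arange(d) - (d - 1) / 2.0
    sigma = d / 3.0
    k1 = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(k1, k1)
    return k / k.sum()


def density_map(
    ens: TrajectoryEnsemble, dx: float, smooth_kernel: int | None = None
) -> ScalarMap:
    """Point density ρ(x_k) = N_k/Δx² in points/μm², optionally smoothed.

    Smoothing convolves with a renormalized d×d Gaussian kernel and
    conserves total mass Σ ρ Δx² = total point count.
    """
    if ens.n_points == 0:
        raise ValueError("empty ensemble")
    grid = Grid.for_ensemble(ens, dx)
    pts = ens.points()
    i, j, valid = grid.bin_index(pts)
    counts = np.zeros((grid.nx, grid.ny), dtype=np.int64)
    np.add.at(counts, (i[valid], j[valid]), 1)
    values = counts / dx**2
    if smooth_kernel is not None and smooth_kernel > 1:
        k = _gaussian_kernel(smooth_kernel)
        # per-source renormalization keeps total mass on the grid even for
        # sources at the edge (their kernel support is clipped)
        mass = convolve(np.ones_like(values, dtype=float), k, mode="constant")
        values = convolve(values.astype(float) / mass, k, mode="constant")
    return ScalarMap(grid, values, counts)


def _binned_moments(ens: TrajectoryEnsemble, grid: Grid):
    disp = ens.displacements()
    i, j, valid = grid.bin_index(disp.origins)
    flat = i[valid] * grid.ny + j[valid]
    dxy = disp.dxy[valid]
    nbins = grid.nx * grid.ny
    counts = np.bincount(flat, minlength=nbins)
    s1 = np.column_stack(
        [np.bincount(flat, weights=dxy[:, u], minlength=nbins) for u in range(2)]
    )
    s2 = {
        (u, v): np.bincount(flat, weights=dxy[:, u] * dxy[:, v], minlength=nbins)
        for u, v in ((0, 0), (0, 1), (1, 1))
    }
    return counts, s1, s2


def drift_map(ens: TrajectoryEnsemble, dx: float, min_disp: int = 15) -> VectorMap:
    """Local drift field a(x_k): mean displacement over Δt, per bin."""
    if min_disp < 1:
        raise ValueError("min_disp must be >= 1")
    grid = Grid.for_ensemble(ens, dx)
    counts, s1, _ = _binned_moments(ens, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        vec = s1 / counts[:, None] / ens.dt
    vec[counts < min_disp] = np.nan
    return VectorMap(
        grid, vec.reshape(grid.nx, grid.ny, 2), counts.reshape(grid.nx, grid.ny)
    )


def diffusion_map(
    ens: TrajectoryEnsemble, dx: float, min_disp: int = 15, tensor: bool = False
):
    """Effective diffusion map from second displacement moments.

    Per bin, D^(u,v) = Σ ΔX_u ΔX_v / (2 N_k Δt).  The scalar map is the
    tensor half-trace (D^(1,1) + D^(2,2))/2; with ``tensor=True`` the
    (nx, ny, 2, 2) tensor field is returned alongside.
    """
    if min_disp < 1:
        raise ValueError("min_disp must be >= 1")
    grid = Grid.for_ensemble(ens, dx)
    counts, _, s2 = _binned_moments(ens, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        d11 = s2[(0, 0)] / counts / (2 * ens.dt)
        d22 = s2[(1, 1)] / counts / (2 * ens.dt)
        d12 = s2[(0, 1)] / counts / (2 * ens.dt)
    mask = counts < min_disp
    for arr in (d11, d22, d12):
        arr[mask] = np.nan
    scalar = ScalarMap(
        grid, ((d11 + d22) / 2).reshape(grid.nx, grid.ny), counts.reshape(grid.nx, grid.ny)
    )
    if not tensor:
        return scalar
    T = np.empty((grid.nx, grid.ny, 2, 2))
    T[..., 0, 0] = d11.reshape(grid.nx, grid.ny)
    T[..., 1, 1] = d22.reshape(grid.nx, grid.ny)
    T[..., 0, 1] = T[..., 1, 0] = d12.reshape(grid.nx, grid.ny)
    return scalar, T


def cosine_weights(dist: np.ndarray, r: float) -> np.ndarray:
    """w = cos(π/2 · d/r): 1 at the center, 0 at the disk edge."""
    return np.cos(0.5 * np.pi * np.clip(dist / r, 0.0, 1.0))


def cosine_filtered_maps(
    ens: TrajectoryEnsemble,
    dx_fine: float,
    r_filt: float,
    min_disp: int = 15,
) -> tuple[VectorMap, ScalarMap]:
    """Cosine-weighted drift and diffusion maps on a refined grid.

    For each fine-bin center x_k, displacements originating in the disk
    D(x_k, r) are weighted by w = cos(π/2 · ‖X − x_k‖/r); the weighted mean
    step gives the drift and the weighted second moments the diffusion.
    Bins whose disk holds fewer than ``min_disp`` displacements are masked.
    """
    if r_filt < dx_fine:
        raise ValueError("filter radius must be at least the bin size")
    grid = Grid.for_ensemble(ens, dx_fine)
    disp = ens.displacements()
    cx, cy = grid.centers()
    centers = np.column_stack([g.ravel() for g in np.meshgrid(cx, cy, indexing="ij")])
    tree = KDTree(disp.origins)
    idx, dists = tree.query_radius(centers, r=r_filt, return_distance=True)
    nb = centers.shape[0]
    vec = np.full((nb, 2), np.nan)
    dmap = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=np.int64)
    for k in range(nb):
        sel = idx[k]
        counts[k] = sel.size
        if sel.size < min_disp:
            continue
        w = cosine_weights(dists[k], r_filt)
        wsum = w.sum()
        if wsum <= 0:
            continue
        steps = disp.dxy[sel]
        vec[k] = (w[:, None] * steps).sum(axis=0) / wsum / ens.dt
        m2 = (w * (steps**2).sum(axis=1)).sum() / wsum
        dmap[k] = m2 / (4.0 * ens.dt)
    shape = (grid.nx, grid.ny)
    return (
        VectorMap(grid, vec.reshape(*shape, 2), counts.reshape(shape)),
        ScalarMap(grid, dmap.reshape(shape), counts.reshape(shape)),
    )
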