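"""Ground-truth trajectory generators.

Every estimator in this package is validated against synthetic data with a
known generating model:

* overdamped Langevin dynamics in a truncated elliptic parabolic potential
  (`simulate_well`),
* Brownian motion reflected at rectangle walls (`simulate_confined`),
* diffusion constrained to a node-tubule network with slower motion inside
  nodes (`simulate_on_graph`),
* two-state switching between ballistic runs and Ornstein-Uhlenbeck
  confinement (`simulate_switching`).

Langevin integration uses the Euler-Maruyama scheme at a fine internal step
``dt_sim`` and subsamples to the observation interval ``dt_obs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj_core import TrajectoryEnsemble, ensemble_from_arrays

__all__ = [
    "WellSpec",
    "SimConfig",
    "SyntheticGraph",
    "simulate_well",
    "simulate_confined",
    "simulate_on_graph",
    "simulate_switching",
    "first_exit_times",
    "two_node_graph",
    "triangle_graph",
    "lattice_graph",
]


@dataclass(frozen=True)
class WellSpec:
    """A truncated elliptic parabolic potential well.

    The potential is U(X) = A[(x'/a)² + (y'/b)² − 1] inside the boundary
    ellipse and 0 outside, with (x', y') the coordinates relative to the
    center μ in the frame rotated by φ.  The well energy is E = A/D in kT.
    """

    center: tuple[float, float]  # μm
    a: float  # large semi-axis, μm
    b: float  # small semi-axis, μm
    phi: float = 0.0  # orientation, rad
    A: float = 0.0  # attraction coefficient, μm²/s
    D: float = 0.1  # diffusion coefficient, μm²/s

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if self.A < 0 or self.D <= 0:
            raise ValueError("need A >= 0 and D > 0")

    @property
    def energy(self) -> float:
        """Well depth E = A/D in units of kT."""
        return self.A / self.D

    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.phi), np.sin(self.phi)
        return np.array([[c, -s], [s, c]])

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized membership test against the boundary ellipse."""
        rel = (np.atleast_2d(xy) - np.asarray(self.center)) @ self.rotation()
        return (rel[:, 0] / self.a) ** 2 + (rel[:, 1] / self.b) ** 2 <= 1.0

    def force(self, xy: np.ndarray) -> np.ndarray:
        """Drift −∇U: linear restoring force inside the ellipse, 0 outside."""
        R = self.rotation()
        rel = (np.atleast_2d(xy) - np.asarray(self.center)) @ R
        f_local = np.empty_like(rel)
        f_local[:, 0] = -2.0 * self.A * rel[:, 0] / self.a**2
        f_local[:, 1] = -2.0 * self.A * rel[:, 1] / self.b**2
        inside = (rel[:, 0] / self.a) ** 2 + (rel[:, 1] / self.b) ** 2 <= 1.0
        f_local[~inside] = 0.0
        return f_local @ R.T


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings.

    ``dt_sim`` defaults to ``dt_obs / 10``; localization noise defaults to
    zero (ground truth is noise-free unless requested).
    """

    dt_obs: float = 0.02  # s
    n_traj: int = 100
    traj_len: int = 100  # observed points per trajectory
    seed: int = 0
    dt_sim: float | None = None  # s; default dt_obs / 10
    loc_noise: float = 0.0  # μm
    domain: tuple[float, float, float, float] | None = None  # reflecting walls

    def __post_init__(self) -> None:
        if self.dt_sim is None:
            object.__setattr__(self, "dt_sim", self.dt_obs / 10.0)
        sub = self.dt_obs / self.dt_sim
        if abs(sub - round(sub)) > 1e-9 or self.dt_sim > self.dt_obs:
            raise ValueError("dt_obs must be an integer multiple of dt_sim")

    @property
    def substeps(self) -> int:
        return int(round(self.dt_obs / self.dt_sim))


def _observe(paths: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> TrajectoryEnsemble:
    """Add localization noise and wrap (n_traj, traj_len, 2) paths."""
    if cfg.loc_noise > 0:
        paths = paths + rng.normal(0.0, cfg.loc_noise, size=paths.shape)
    return ensemble_from_arrays(list(paths), cfg.dt_obs)


def simulate_well(spec: WellSpec, cfg: SimConfig) -> TrajectoryEnsemble:
    """Langevin trajectories dX = −∇U dt + √(2D) dW in a parabolic well.

    Outside the boundary ellipse the drift vanishes, so escaped particles
    diffuse freely.  Without a ``cfg.domain``, trajectories start uniformly
    inside the boundary ellipse; with a reflecting rectangular domain they
    start uniformly over the domain, reproducing the usual SPT situation of
    a nanodomain embedded in a larger observed region, with molecules
    escaping and being recaptured.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_traj
    if cfg.domain is not None:
        lo = np.array(cfg.domain[:2], dtype=float)
        hi = np.array(cfg.domain[2:], dtype=float)
        x = lo + rng.random((n, 2)) * (hi - lo)
    else:
        lo = hi = None
        x = _uniform_in_ellipse(spec, n, rng)
    paths = np.empty((n, cfg.traj_len, 2))
    paths[:, 0] = x
    sigma = np.sqrt(2.0 * spec.D * cfg.dt_sim)
    for j in range(1, cfg.traj_len):
        for _ in range(cfg.substeps):
            x = x + spec.force(x) * cfg.dt_sim + sigma * rng.standard_normal((n, 2))
            if lo is not None:
                x = _reflect(x, lo, hi)
        paths[:, j] = x
    return _observe(paths, cfg, rng)


def _uniform_in_ellipse(spec: WellSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    u = np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    local = np.column_stack([spec.a * u * np.cos(th), spec.b * u * np.sin(th)])
    return local @ spec.rotation().T + np.asarray(spec.center)


def first_exit_times(spec: WellSpec, n: int, seed: int, dt_sim: float, t_max: float) -> np.ndarray:
    """Monte-Carlo first exit times from the well boundary, started at μ.

    Returns the exit times of the particles that escaped before ``t_max``
    (censored particles are excluded; choose t_max several times the
    expected residence time).
    """
    rng = np.random.default_rng(seed)
    x = np.tile(np.asarray(spec.center, dtype=float), (n, 1))
    alive = np.arange(n)
    exit_t = np.full(n, np.nan)
    sigma = np.sqrt(2.0 * spec.D * dt_sim)
    n_steps = int(np.ceil(t_max / dt_sim))
    for step in range(1, n_steps + 1):
        x = x + spec.force(x) * dt_sim + sigma * rng.standard_normal((alive.size, 2))
        out = ~spec.contains(x)
        if np.any(out):
            exit_t[alive[out]] = step * dt_sim
            x = x[~out]
            alive = alive[~out]
            if alive.size == 0:
                break
    return exit_t[np.isfinite(exit_t)]


def simulate_confined(
    domain: tuple[float, float, float, float], D: float, cfg: SimConfig
) -> TrajectoryEnsemble:
    """Brownian motion with reflecting walls at a rectangle boundary.

    ``domain`` is (xmin, ymin, xmax, ymax) in μm.  Reflection is by
    coordinate mirroring at the walls.  A null model against which the
    potential-well detectors are benchmarked.
    """
    xmin, ymin, xmax, ymax = map(float, domain)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate domain")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_traj
    lo = np.array([xmin, ymin])
    hi = np.array([xmax, ymax])
    span = hi - lo
    x = lo + rng.random((n, 2)) * span
    paths = np.empty((n, cfg.traj_len, 2))
    paths[:, 0] = x
    sigma = np.sqrt(2.0 * D * cfg.dt_sim)
    for j in range(1, cfg.traj_len):
        for _ in range(cfg.substeps):
            x = x + sigma * rng.standard_normal((n, 2))
            x = _reflect(x, lo, hi)
        paths[:, j] = x
    return _observe(paths, cfg, rng)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


# ---------------------------------------------------------------------------
# network-constrained diffusion


@dataclass(frozen=True)
class SyntheticGraph:
    """A planar node-tubule network: node disks joined by straight tubules."""

    nodes: np.ndarray  # (K, 2) centers, μm
    radii: np.ndarray  # (K,) node radii, μm
    edges: tuple[tuple[int, int], ...]
    tubule_width: float = 0.1  # full width, μm

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if np.any(radii <= 0):
            raise ValueError("node radii must be positive")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "radii", radii)

    def region(self):
        """Shapely union of node disks and tubule rectangles."""
        from shapely.geometry import LineString, Point
        from shapely.ops import unary_union

        parts = [Point(*c).buffer(r, quad_segs=32) for c, r in zip(self.nodes, self.radii)]
        for i, j in self.edges:
            parts.append(
                LineString([self.nodes[i], self.nodes[j]]).buffer(
                    self.tubule_width / 2.0, quad_segs=8
                )
            )
        return unary_union(parts)

    def in_node(self, xy: np.ndarray) -> np.ndarray:
        """Boolean: is each point inside any node disk."""
        d2 = ((xy[:, None, :] - self.nodes[None, :, :]) ** 2).sum(axis=2)
        return np.any(d2 <= self.radii[None, :] ** 2, axis=1)


def two_node_graph(dist: float = 0.7, radius: float = 0.25, width: float = 0.15) -> SyntheticGraph:
    return SyntheticGraph(
        np.array([[0.0, 0.0], [dist, 0.0]]), np.array([radius, radius]), ((0, 1),), width
    )


def triangle_graph(side: float = 0.7, radius: float = 0.25, width: float = 0.15) -> SyntheticGraph:
    nodes = np.array([[0.0, 0.0], [side, 0.0], [side / 2, side * np.sqrt(3) / 2]])
    return SyntheticGraph(nodes, np.full(3, radius), ((0, 1), (1, 2), (0, 2)), width)


def lattice_graph(
    rows: int = 2, cols: int = 5, pitch: float = 0.7, radius: float = 0.25, width: float = 0.15
) -> SyntheticGraph:
    """Rectangular grid of rows × cols nodes with nearest-neighbour tubules."""
    nodes = np.array([[c * pitch, r * pitch] for r in range(rows) for c in range(cols)])
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.append((i, i + 1))
            if r + 1 < rows:
                edges.append((i, i + cols))
    return SyntheticGraph(nodes, np.full(rows * cols, radius), tuple(edges), width)


def simulate_on_graph(
    g: SyntheticGraph, D: float, node_dwell_bias: float, cfg: SimConfig
) -> TrajectoryEnsemble:
    """Diffusion constrained to the node-tubule region.

    Inside a node disk the diffusion coefficient is ``D / node_dwell_bias``,
    so a bias > 1 slows particles down in nodes and concentrates trajectory
    points there — the density contrast the graph-reconstruction algorithm
    relies on.  Steps leaving the region are rejected (the particle waits).
    """
    from shapely import contains_xy, prepare

    if node_dwell_bias <= 0:
        raise ValueError("node_dwell_bias must be positive")
    region = g.region()
    prepare(region)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_traj
    # start at node centers, round-robin
    x = g.nodes[np.arange(n) % len(g.nodes)].astype(float).copy()
    paths = np.empty((n, cfg.traj_len, 2))
    paths[:, 0] = x
    for j in range(1, cfg.traj_len):
        for _ in range(cfg.substeps):
            d_eff = np.where(g.in_node(x), D / node_dwell_bias, D)
            prop = x + np.sqrt(2.0 * d_eff * cfg.dt_sim)[:, None] * rng.standard_normal((n, 2))
            ok = contains_xy(region, prop[:, 0], prop[:, 1])
            x = np.where(ok[:, None], prop, x)
        paths[:, j] = x
    return _observe(paths, cfg, rng)


# ---------------------------------------------------------------------------
# two-state switching motion


def simulate_switching(
    v_fast: float,
    ou: WellSpec,
    rate_on: float,
    rate_off: float,
    cfg: SimConfig,
    start_confined: bool = True,
) -> tuple[TrajectoryEnsemble, dict]:
    """Two-state Markov motion: ballistic runs alternate with OU confinement.

    Parameters
    ----------
    v_fast : float
        Run speed in μm/s; each run has a fresh uniformly random direction.
    ou : WellSpec
        Confinement parameters: λ per axis = 2A/a² (isotropic when a = b)
        and diffusion D.  The confinement is anchored at the position where
        the particle enters the confined state.
    rate_on, rate_off : float
        Switching rates (s⁻¹): directed → confined and confined → directed.
        State dwell times are exponential with means 1/rate.

    Returns the ensemble and a ground-truth dict with the per-trajectory
    state sequences and the completed confined dwell durations.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.dt_obs
    lam = 2.0 * ou.A / ou.a**2  # isotropic spring constant
    decay = np.exp(-lam * dt)
    sd_eq = np.sqrt(ou.D * (1.0 - decay**2) / lam) if lam > 0 else np.sqrt(2 * ou.D * dt)

    def dwell_steps(rate: float) -> int:
        if rate <= 0:
            return np.iinfo(np.int64).max
        return max(1, int(np.ceil(rng.exponential(1.0 / rate) / dt)))

    paths = np.empty((cfg.n_traj, cfg.traj_len, 2))
    states = np.empty((cfg.n_traj, cfg.traj_len), dtype=np.int8)  # 1 = confined
    confined_dwells: list[float] = []
    for i in range(cfg.n_traj):
        x = rng.normal(0.0, 1.0, 2)
        confined = start_confined
        anchor = x.copy()
        remaining = dwell_steps(rate_off if confined else rate_on)
        run_dir = _rand_dir(rng)
        steps_in_state = 0
        for j in range(cfg.traj_len):
            paths[i, j] = x
            states[i, j] = 1 if confined else 0
            if confined:
                x = anchor + (x - anchor) * decay + sd_eq * rng.standard_normal(2)
            else:
                x = x + v_fast * dt * run_dir
            steps_in_state += 1
            remaining -= 1
            if remaining == 0 and j < cfg.traj_len - 1:
                if confined:
                    confined_dwells.append(steps_in_state * dt)
                confined = not confined
                steps_in_state = 0
                if confined:
                    anchor = x.copy()
                else:
                    run_dir = _rand_dir(rng)
                remaining = dwell_steps(rate_off if confined else rate_on)
    ens = _observe(paths, cfg, rng)
    truth = {"states": states, "confined_dwells": np.asarray(confined_dwells)}
    return ens, truth


def _rand_dir(rng: np.random.Generator) -> np.ndarray:
    th = rng.random() * 2 * np.pi
    return np.array([np.cos(th), np.sin(th)])
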