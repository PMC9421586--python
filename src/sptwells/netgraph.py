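"""Graph reconstruction of organelle networks from trajectories.

Particles exploring a node-tubule network (e.g. the ER) spend more time in
nodes than in tubules, and move more slowly there.  The recursive
velocity-based graph reconstruction algorithm (GRA) exploits this:

1. keep trajectory points whose instantaneous speed is below a threshold
   v_th (slow points);
2. cluster them with DBSCAN using the loosest parameter pair (R_U, N_1);
3. recursively re-cluster any cluster larger than ``max_clust_npts`` with
   successively stricter (R_u, N_v) pairs;
4. fit a boundary (confidence ellipse or convex hull) per cluster and
   assign the discarded fast points falling inside a boundary to it;
5. iteratively merge overlapping clusters.

Tubules are then read off a connectivity matrix C whose entry c_ij counts
first- and second-order trajectory traversals from node i to node j
(consecutive points, or with one off-node point in between).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN

from .traj_core import TrajectoryEnsemble
from .wells import Ellipse, confidence_ellipse

__all__ = [
    "NetworkNode",
    "NetworkGraph",
    "GRAParams",
    "reconstruct_graph",
    "network_stats",
    "resynchronize_exits",
    "suggest_velocity_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class NetworkNode:
    """A reconstructed network node: a cluster of slow trajectory points."""

    id: int
    points: np.ndarray  # (m, 2) member points, μm
    boundary: object  # Ellipse or shapely Polygon

    @property
    def center(self) -> tuple[float, float]:
        c = self.points.mean(axis=0)
        return float(c[0]), float(c[1])

    @property
    def area(self) -> float:
        if isinstance(self.boundary, Ellipse):
            return self.boundary.area
        return float(self.boundary.area)

    def polygon(self):
        if isinstance(self.boundary, Ellipse):
            return self.boundary.polygon()
        return self.boundary

    def contains(self, xy: np.ndarray) -> np.ndarray:
        if isinstance(self.boundary, Ellipse):
            return self.boundary.contains(xy)
        from shapely import contains_xy

        xy = np.atleast_2d(xy)
        return contains_xy(self.boundary, xy[:, 0], xy[:, 1])


@dataclass
class NetworkGraph:
    """Nodes plus traversal-count connectivity."""

    nodes: list[NetworkNode]
    C: np.ndarray  # symmetrized traversal counts, (K, K)
    C_directed: np.ndarray  # raw directional counts
    min_count: int = 1

    @property
    def edges(self) -> list[tuple[int, int]]:
        K = len(self.nodes)
        return [
            (i, j)
            for i in range(K)
            for j in range(i + 1, K)
            if self.C[i, j] >= self.min_count
        ]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.id, x=node.center[0], y=node.center[1], area=node.area,
                       n_points=len(node.points))
        for i, j in self.edges:
            ci, cj = self.nodes[i].center, self.nodes[j].center
            g.add_edge(
                self.nodes[i].id,
                self.nodes[j].id,
                count=int(self.C[i, j]),
                length=float(np.hypot(ci[0] - cj[0], ci[1] - cj[1])),
            )
        return g


@dataclass(frozen=True)
class GRAParams:
    """Parameters of the recursive graph reconstruction.

    ``radii`` is consumed from the largest to the smallest and
    ``min_counts`` from the smallest to the largest as the recursion
    tightens; when the ladders differ in length the shorter one cycles.
    """

    v_th: float | None = None  # μm/s; None → antimode of the speed distribution
    radii: tuple[float, ...] = (0.15, 0.10, 0.06)  # R ladder, μm, loosest first
    min_counts: tuple[int, ...] = (10, 20, 40)  # N ladder (N_1 .. N_V)
    max_clust_npts: int = 1000  # maxClustNpts
    boundary_mode: str = "hull"  # or "ellipsoid" (confidence ellipse)
    ell_perc: float = 95.0
    min_count: int = 1  # traversal count required for an edge
    min_cluster_size: int = 10


def suggest_velocity_threshold(speeds: np.ndarray, n_bins: int = 128) -> float:
    """Speed threshold separating the slow and fast motion components.

    Otsu's criterion on the speed histogram: the threshold minimizing the
    intra-class variance of the two resulting speed classes.  Robust even
    when the two components overlap heavily and no clear antimode exists.
    """
    speeds = np.asarray(speeds, dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if speeds.size == 0:
        raise ValueError("no speeds")
    hist, edges = np.histogram(speeds, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    if total == 0:
        return float(np.median(speeds))
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    w0 = cum_w / total
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cum_m / cum_w
        mu1 = (cum_m[-1] - cum_m) / (total - cum_w)
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between[:-1]))
    return float(edges[k + 1])


def _param_ladder(p: GRAParams):
    """(R_u, N_v) pairs from strict start (after the initial pass) onwards."""
    radii = list(p.radii)[1:] if len(p.radii) > 1 else [p.radii[0]]
    counts = list(p.min_counts)[1:] if len(p.min_counts) > 1 else [p.min_counts[0]]
    n = max(len(radii), len(counts))
    return [(radii[min(i, len(radii) - 1)], counts[min(i, len(counts) - 1)]) for i in range(n)]


def _recursive_cluster(pts: np.ndarray, p: GRAParams) -> list[np.ndarray]:
    """DBSCAN with the loosest pair, then refine oversized clusters."""
    labels = DBSCAN(eps=p.radii[0], min_samples=p.min_counts[0]).fit_predict(pts)
    clusters = [np.flatnonzero(labels == k) for k in range(labels.max() + 1)]
    ladder = _param_ladder(p)
    out: list[np.ndarray] = []
    stack = [(idx, 0) for idx in clusters]
    while stack:
        idx, depth = stack.pop()
        if idx.size <= p.max_clust_npts or depth >= len(ladder):
            if idx.size >= p.min_cluster_size:
                out.append(idx)
            continue
        eps, min_samples = ladder[depth]
        sub = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts[idx])
        nsub = sub.max() + 1
        if nsub <= 0:
            out.append(idx)  # indivisible at this strictness
            continue
        if nsub == 1 and np.count_nonzero(sub == 0) == idx.size:
            # no progress; try a stricter pair on the same cluster
            stack.append((idx, depth + 1))
            continue
        for k in range(nsub):
            stack.append((idx[sub == k], depth + 1))
    return out


def _fit_boundary(pts: np.ndarray, p: GRAParams):
    if p.boundary_mode == "hull":
        from shapely.geometry import MultiPoint

        return MultiPoint(pts).convex_hull.buffer(0.0)
    try:
        return confidence_ellipse(pts, p.ell_perc)
    except ValueError:
        from shapely.geometry import MultiPoint

        return MultiPoint(pts).convex_hull.buffer(1e-6)


def _poly(boundary):
    return boundary.polygon() if isinstance(boundary, Ellipse) else boundary


def reconstruct_graph(ens: TrajectoryEnsemble, p: GRAParams = GRAParams()) -> NetworkGraph:
    """Run the recursive velocity-based graph reconstruction."""
    disp = ens.displacements()
    if len(disp) == 0:
        logger.warning("no displacements; empty graph")
        return NetworkGraph([], np.zeros((0, 0)), np.zeros((0, 0)), p.min_count)
    v_th = p.v_th if p.v_th is not None else suggest_velocity_threshold(disp.speeds)
    slow = disp.speeds <= v_th
    slow_pts = disp.origins[slow]
    if slow_pts.shape[0] == 0:
        logger.warning("no slow points below v_th=%.3g; empty graph", v_th)
        return NetworkGraph([], np.zeros((0, 0)), np.zeros((0, 0)), p.min_count)

    clusters = _recursive_cluster(slow_pts, p)
    members = [slow_pts[idx] for idx in clusters]
    boundaries = [_fit_boundary(m, p) for m in members]

    # assign discarded (fast / noise) points to an enclosing boundary
    all_pts = ens.points()
    used = np.zeros(all_pts.shape[0], dtype=bool)
    extra = [[] for _ in members]
    for bi, b in enumerate(boundaries):
        inside = (
            b.contains(all_pts)
            if isinstance(b, Ellipse)
            else _shapely_contains(b, all_pts)
        )
        take = inside & ~used
        extra[bi] = all_pts[take]
        used |= inside
    members = [
        np.concatenate([m, e]) if len(e) else m for m, e in zip(members, extra)
    ]

    # iterative merging of overlapping boundaries
    merged = True
    while merged:
        merged = False
        polys = [_poly(_fit_boundary(m, p)) for m in members]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if polys[i].intersects(polys[j]):
                    members[i] = np.concatenate([members[i], members[j]])
                    del members[j]
                    merged = True
                    break
            if merged:
                break
    boundaries = [_fit_boundary(m, p) for m in members]
    nodes = [NetworkNode(i, m, b) for i, (m, b) in enumerate(zip(members, boundaries))]

    C_dir = _connectivity(ens, nodes)
    C = C_dir + C_dir.T
    return NetworkGraph(nodes, C, C_dir, p.min_count)


def _shapely_contains(geom, pts: np.ndarray) -> np.ndarray:
    from shapely import contains_xy

    return contains_xy(geom, pts[:, 0], pts[:, 1])


def _connectivity(ens: TrajectoryEnsemble, nodes: list[NetworkNode]) -> np.ndarray:
    """First- and second-order traversal counts between nodes."""
    K = len(nodes)
    C = np.zeros((K, K), dtype=np.int64)
    if K == 0:
        return C
    for tr in ens.trajectories:
        member = np.full(len(tr), -1, dtype=np.int64)
        for node in nodes:
            inside = node.contains(tr.xy)
            member[inside & (member < 0)] = node.id
        m = member
        # first order: consecutive points in different nodes
        a, b = m[:-1], m[1:]
        sel = (a >= 0) & (b >= 0) & (a != b)
        np.add.at(C, (a[sel], b[sel]), 1)
        # second order: node, off-node, node
        if len(tr) >= 3:
            a2, mid, b2 = m[:-2], m[1:-1], m[2:]
            sel2 = (a2 >= 0) & (mid < 0) & (b2 >= 0) & (a2 != b2)
            np.add.at(C, (a2[sel2], b2[sel2]), 1)
    return C


def network_stats(g: NetworkGraph) -> dict:
    """Tubule-length, node-area, and degree distributions."""
    if not g.nodes:
        raise ValueError("empty graph")
    centers = np.array([n.center for n in g.nodes])
    lengths = [
        float(np.hypot(*(centers[i] - centers[j]))) for i, j in g.edges
    ]
    areas = [n.area for n in g.nodes]
    deg = np.zeros(len(g.nodes), dtype=int)
    for i, j in g.edges:
        deg[i] += 1
        deg[j] += 1
    return {
        "tubule_lengths": np.asarray(lengths),
        "node_areas": np.asarray(areas),
        "degrees": deg,
    }


def resynchronize_exits(
    ens: TrajectoryEnsemble,
    g: NetworkGraph,
    node: int,
    horizon: float,
    min_inside: int = 3,
) -> dict:
    """Re-origin trajectories at their exit from a chosen node.

    An exit is the first point outside the node boundary after at least
    ``min_inside`` consecutive points inside (suppressing boundary jitter).
    Returns the dispersion curve d̄(τ): the mean over exit events of the
    distance from the exit point at lag τ after exit, together with the
    per-event exit speeds.
    """
    target = next((n for n in g.nodes if n.id == node), None)
    if target is None:
        raise KeyError(f"no node {node}")
    lags = np.arange(1, int(np.floor(horizon / ens.dt)) + 1)
    sums = np.zeros(lags.size)
    counts = np.zeros(lags.size, dtype=np.int64)
    exit_speeds = []
    n_exits = 0
    for tr in ens.trajectories:
        inside = target.contains(tr.xy)
        run = 0
        j = 0
        while j < len(tr):
            if inside[j]:
                run += 1
                j += 1
                continue
            if run >= min_inside:
                # j is the first point outside after a genuine visit
                n_exits += 1
                x_exit = tr.xy[j]
                exit_speeds.append(
                    float(np.hypot(*(tr.xy[j] - tr.xy[j - 1])) / ens.dt)
                )
                avail = len(tr) - 1 - j
                L = min(lags.size, avail)
                if L > 0:
                    d = np.hypot(
                        tr.xy[j + 1 : j + 1 + L, 0] - x_exit[0],
                        tr.xy[j + 1 : j + 1 + L, 1] - x_exit[1],
                    )
                    sums[:L] += d
                    counts[:L] += 1
            run = 0
            j += 1
    with np.errstate(invalid="ignore"):
        curve = sums / counts
    return {
        "lag": lags * ens.dt,
        "dispersion": curve,
        "exit_speeds": np.asarray(exit_speeds),
        "n_exits": n_exits,
    }
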