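import numpy as np
import pytest

from sptwells.netgraph import (
    GRAParams,
    NetworkGraph,
    NetworkNode,
    network_stats,
    reconstruct_graph,
    resynchronize_exits,
    suggest_velocity_threshold,
)
from sptwells.simulate import (
    SimConfig,
    simulate_on_graph,
    triangle_graph,
    two_node_graph,
)
from sptwells.traj_core import ensemble_from_arrays
from sptwells.wells import Ellipse


@pytest.fixture(scope="module")
def two_node_ens():
    g = two_node_graph()
    cfg = SimConfig(dt_obs=0.05, n_traj=80, traj_len=250, seed=3, dt_sim=0.005)
    return g, simulate_on_graph(g, 0.08, 6.0, cfg)


def _map_edges(g_true, rec):
    centers = np.array([n.center for n in rec.nodes])
    m = {i: int(np.argmin(np.hypot(*(g_true.nodes - c).T))) for i, c in enumerate(centers)}
    return {(min(m[i], m[j]), max(m[i], m[j])) for i, j in rec.edges if m[i] != m[j]}


class TestReconstruction:
    def test_two_node_benchmark(self, two_node_ens):
        g, ens = two_node_ens
        rec = reconstruct_graph(ens, GRAParams())
        assert len(rec.nodes) == 2
        assert _map_edges(g, rec) == {(0, 1)}
        for node in rec.nodes:
            d = np.hypot(*(g.nodes - np.array(node.center)).T).min()
            assert d < 0.25  # within one node radius of a true center

    def test_triangle_benchmark(self):
        g = triangle_graph()
        cfg = SimConfig(dt_obs=0.05, n_traj=120, traj_len=250, seed=5, dt_sim=0.005)
        ens = simulate_on_graph(g, 0.08, 6.0, cfg)
        rec = reconstruct_graph(ens, GRAParams())
        assert len(rec.nodes) == 3
        assert _map_edges(g, rec) == {(0, 1), (0, 2), (1, 2)}

    def test_single_blob_gives_one_node_no_edges(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 0.1, (900, 2))
        paths = [pts[i : i + 10] for i in range(0, 900, 10)]
        ens = ensemble_from_arrays(paths, 0.05)
        rec = reconstruct_graph(ens, GRAParams(v_th=10.0))
        assert len(rec.nodes) == 1
        assert rec.edges == []

    def test_no_slow_points_gives_empty_graph(self):
        rng = np.random.default_rng(1)
        paths = [np.cumsum(rng.normal(2, 0.5, (10, 2)), axis=0) for _ in range(10)]
        ens = ensemble_from_arrays(paths, 0.05)
        rec = reconstruct_graph(ens, GRAParams(v_th=1e-6))
        assert rec.nodes == []

    def test_connectivity_symmetric_and_bounded(self, two_node_ens):
        g, ens = two_node_ens
        rec = reconstruct_graph(ens, GRAParams())
        np.testing.assert_array_equal(rec.C, rec.C.T)
        assert rec.C.sum() <= 2 * len(ens.displacements())

    def test_recursion_caps_cluster_sizes(self, two_node_ens):
        _, ens = two_node_ens
        rec = reconstruct_graph(ens, GRAParams(max_clust_npts=400))
        # clusters either respect the cap or were indivisible at the
        # strictest ladder pair (then they at least stayed as single nodes)
        assert len(rec.nodes) >= 2


class TestStats:
    def _toy_graph(self):
        n0 = NetworkNode(0, np.zeros((5, 2)), Ellipse((0, 0), 0.2, 0.2, 0))
        n1 = NetworkNode(1, np.zeros((5, 2)) + [1, 0], Ellipse((1, 0), 0.2, 0.2, 0))
        n2 = NetworkNode(2, np.zeros((5, 2)) + [5, 5], Ellipse((5, 5), 0.2, 0.2, 0))
        C = np.zeros((3, 3), int)
        C[0, 1] = C[1, 0] = 4
        return NetworkGraph([n0, n1, n2], C, C)

    def test_tubule_length_between_connected_nodes(self):
        st = network_stats(self._toy_graph())
        np.testing.assert_allclose(st["tubule_lengths"], [1.0])

    def test_unconnected_node_contributes_no_length(self):
        st = network_stats(self._toy_graph())
        assert st["degrees"].tolist() == [1, 1, 0]

    def test_circular_node_area(self):
        # hull of a dense ring of radius 0.2 ~ pi r^2
        rng = np.random.default_rng(2)
        th = rng.random(600) * 2 * np.pi
        pts = 0.2 * np.column_stack([np.cos(th), np.sin(th)])
        from shapely.geometry import MultiPoint

        node = NetworkNode(0, pts, MultiPoint(pts).convex_hull)
        assert node.area == pytest.approx(np.pi * 0.04, rel=0.05)


class TestResynchronization:
    def _graph_with_disk_node(self, center=(0.0, 0.0), r=0.3):
        node = NetworkNode(0, np.zeros((5, 2)), Ellipse(center, r, r, 0.0))
        return NetworkGraph([node], np.zeros((1, 1), int), np.zeros((1, 1), int))

    def test_ballistic_exits_linear_dispersion(self):
        g = self._graph_with_disk_node()
        v, dt = 2.0, 0.05
        paths = []
        for k in range(8):
            th = k * np.pi / 4
            d = np.array([np.cos(th), np.sin(th)])
            paths.append(np.outer(np.arange(40) * v * dt, d))  # start at center
        ens = ensemble_from_arrays(paths, dt)
        res = resynchronize_exits(ens, g, 0, horizon=0.5)
        assert res["n_exits"] == 8
        np.testing.assert_allclose(res["dispersion"], v * res["lag"], rtol=1e-9)
        np.testing.assert_allclose(res["exit_speeds"], v)

    def test_brownian_exits_sqrt_time_dispersion(self):
        rng = np.random.default_rng(3)
        dt, D = 0.05, 0.1
        g = self._graph_with_disk_node(r=0.2)
        paths = []
        for _ in range(400):
            steps = rng.normal(0, np.sqrt(2 * D * dt), (200, 2))
            paths.append(np.cumsum(np.vstack([[0, 0], steps]), axis=0))
        ens = ensemble_from_arrays(paths, dt)
        res = resynchronize_exits(ens, g, 0, horizon=1.0)
        # mean distance of 2-D Brownian motion: sqrt(pi D t)
        lag = res["lag"]
        pred = np.sqrt(np.pi * D * lag)
        ratio = res["dispersion"][3:10] / pred[3:10]
        assert np.all(np.abs(ratio - 1) < 0.25)

    def test_missing_node_raises(self):
        g = self._graph_with_disk_node()
        ens = ensemble_from_arrays([np.zeros((5, 2))], 0.05)
        with pytest.raises(KeyError):
            resynchronize_exits(ens, g, 7, horizon=1.0)


class TestVelocityThreshold:
    def test_separates_bimodal_speeds(self):
        rng = np.random.default_rng(4)
        speeds = np.concatenate([
            rng.normal(0.5, 0.1, 4000).clip(0.01),
            rng.normal(2.5, 0.3, 2000),
        ])
        v = suggest_velocity_threshold(speeds)
        assert 0.8 < v < 2.2
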