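import numpy as np
import pytest

from sptwells.simulate import (
    SimConfig,
    WellSpec,
    first_exit_times,
    lattice_graph,
    simulate_confined,
    simulate_on_graph,
    simulate_switching,
    simulate_well,
    triangle_graph,
    two_node_graph,
)
from sptwells.wells import residence_time


class TestWellSimulator:
    def test_fixed_seed_reproducible(self):
        spec = WellSpec((0, 0), 0.2, 0.2, 0.0, 0.3, 0.1)
        cfg = SimConfig(n_traj=10, traj_len=20, seed=5)
        a = simulate_well(spec, cfg)
        b = simulate_well(spec, cfg)
        np.testing.assert_array_equal(a.points(), b.points())

    def test_zero_attraction_is_brownian(self):
        spec = WellSpec((0, 0), 0.2, 0.2, 0.0, 0.0, 0.1)
        cfg = SimConfig(dt_obs=0.02, n_traj=500, traj_len=20, seed=6)
        ens = simulate_well(spec, cfg)
        d = ens.displacements()
        msd_axis = np.mean(d.dxy**2, axis=0)
        np.testing.assert_allclose(msd_axis, 2 * 0.1 * 0.02, rtol=0.05)

    def test_stationary_density_peaks_at_center(self):
        spec = WellSpec((0.5, -0.3), 0.2, 0.2, 0.0, 0.3, 0.1)
        cfg = SimConfig(dt_obs=0.02, n_traj=200, traj_len=200, seed=7)
        ens = simulate_well(spec, cfg)
        pts = ens.points()
        bins = 0.05
        H, xe, ye = np.histogram2d(
            pts[:, 0], pts[:, 1], bins=[np.arange(-0.2, 1.2, bins), np.arange(-1.0, 0.4, bins)]
        )
        i, j = np.unravel_index(np.argmax(H), H.shape)
        mode = (xe[i] + bins / 2, ye[j] + bins / 2)
        assert abs(mode[0] - 0.5) <= bins and abs(mode[1] + 0.3) <= bins

    def test_mle_recovers_spring_constant_inside_well(self):
        # lambda = 2A/a² = 15 1/s for A=0.3, a=0.2
        from sptwells.wells import ou_mle

        spec = WellSpec((0, 0), 0.2, 0.2, 0.0, 0.3, 0.1)
        cfg = SimConfig(dt_obs=0.01, n_traj=300, traj_len=60, seed=8, dt_sim=0.0002)
        ens = simulate_well(spec, cfg)
        d = ens.displacements()
        p0, p1 = d.origins, d.origins + d.dxy
        # select on the origin only: conditioning the endpoint too would
        # bias the regression toward inward steps
        inner = np.hypot(p0[:, 0], p0[:, 1]) < 0.1
        assert inner.sum() > 3000
        fit = ou_mle(p0[inner], p1[inner], ens.dt, mu=(0.0, 0.0))
        assert np.mean(fit.lam) == pytest.approx(15.0, rel=0.2)

    def test_residence_time_against_escape_formula(self):
        # E = 4 kT well: empirical mean first exit within 30 % of formula
        spec = WellSpec((0, 0), 0.15, 0.15, 0.0, 0.4, 0.1)
        tau = residence_time(0.15, 0.15, 0.4, 0.1)
        exits = first_exit_times(spec, n=300, seed=9, dt_sim=2e-5, t_max=tau * 8)
        assert tau == pytest.approx(exits.mean(), rel=0.3)


class TestConfined:
    def test_stays_inside_domain(self):
        ens = simulate_confined((0, 0, 1, 0.5), 0.2, SimConfig(n_traj=50, traj_len=50, seed=1))
        pts = ens.points()
        assert pts[:, 0].min() >= 0 and pts[:, 0].max() <= 1
        assert pts[:, 1].min() >= 0 and pts[:, 1].max() <= 0.5

    def test_large_domain_short_time_is_free_diffusion(self):
        D = 0.1
        ens = simulate_confined((-50, -50, 50, 50), D, SimConfig(dt_obs=0.02, n_traj=500, traj_len=10, seed=2))
        msd = np.mean(np.sum(ens.displacements().dxy ** 2, axis=1))
        assert msd / (4 * 0.02) == pytest.approx(D, rel=0.1)

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            simulate_confined((0, 0, 0, 1), 0.1, SimConfig(seed=0))


class TestGraphSimulator:
    def test_points_stay_on_network(self):
        g = triangle_graph()
        cfg = SimConfig(dt_obs=0.05, n_traj=20, traj_len=50, seed=3, dt_sim=0.005)
        ens = simulate_on_graph(g, 0.08, 6.0, cfg)
        from shapely import contains_xy

        region = g.region().buffer(1e-9)
        pts = ens.points()
        assert contains_xy(region, pts[:, 0], pts[:, 1]).all()

    def test_dwell_bias_concentrates_points_in_nodes(self):
        g = two_node_graph()
        cfg = SimConfig(dt_obs=0.05, n_traj=30, traj_len=100, seed=4, dt_sim=0.005)
        biased = simulate_on_graph(g, 0.08, 6.0, cfg)
        neutral = simulate_on_graph(g, 0.08, 1.0, cfg)
        f_b = g.in_node(biased.points()).mean()
        f_n = g.in_node(neutral.points()).mean()
        assert f_b > f_n

    def test_lattice_factory_topology(self):
        g = lattice_graph(2, 5)
        assert len(g.nodes) == 10
        assert len(g.edges) == 13  # 2*4 horizontal + 5 vertical


class TestSwitching:
    def _ou(self):
        return WellSpec((0, 0), 0.05, 0.05, 0.0, 0.0125, 0.01)

    def test_rate_off_zero_stays_confined(self):
        cfg = SimConfig(dt_obs=0.1, n_traj=5, traj_len=100, seed=5, dt_sim=0.1)
        ens, truth = simulate_switching(1.0, self._ou(), rate_on=0.5, rate_off=0.0, cfg=cfg)
        assert (truth["states"] == 1).all()
        # trajectory never leaves a small neighbourhood
        for tr in ens:
            assert np.hypot(*(tr.xy - tr.xy.mean(axis=0)).T).max() < 0.3

    def test_rate_on_zero_stays_directed(self):
        cfg = SimConfig(dt_obs=0.1, n_traj=5, traj_len=100, seed=6, dt_sim=0.1)
        ens, truth = simulate_switching(
            1.0, self._ou(), rate_on=0.0, rate_off=0.2, cfg=cfg, start_confined=False
        )
        assert (truth["states"] == 0).all()
        from sptwells.lyso import detect_confinements

        assert detect_confinements(ens, 10, 0.3) == []

    def test_dwell_times_exponential_with_requested_mean(self):
        cfg = SimConfig(dt_obs=0.1, n_traj=50, traj_len=1000, seed=7, dt_sim=0.1)
        _, truth = simulate_switching(1.0, self._ou(), 0.5, 0.2, cfg)
        d = truth["confined_dwells"]
        assert d.size >= 300
        assert d.mean() == pytest.approx(5.0, rel=0.25)
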