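import numpy as np
import pytest

from sptwells.wells import (
    Ellipse,
    brownian_loglik_1d,
    chi2_quantile,
    confidence_ellipse,
    moment_lambda,
    ou_loglik_1d,
    ou_mle,
    ou_mle_1d,
    parabolic_index,
    residence_time,
)


def _ou_path(lam, D, dt, n, mu=0.0, seed=0):
    rng = np.random.default_rng(seed)
    th = np.exp(-lam * dt)
    sd = np.sqrt(D * (1 - th**2) / lam)
    x = np.empty(n + 1)
    x[0] = mu
    for i in range(n):
        x[i + 1] = mu + (x[i] - mu) * th + sd * rng.standard_normal()
    return x


class TestConfidenceEllipse:
    @pytest.mark.parametrize(
        "conf,psi", [(90, 4.605), (95, 5.991), (99, 9.210)]
    )
    def test_chi2_scale_factors(self, conf, psi):
        assert chi2_quantile(conf) == pytest.approx(psi, abs=5e-4)

    def test_isotropic_gaussian_gives_circle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (20000, 2))
        e = confidence_ellipse(pts, 95)
        assert e.a == pytest.approx(np.sqrt(5.991), rel=0.03)
        assert e.b == pytest.approx(np.sqrt(5.991), rel=0.03)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (500, 2)) * [2.0, 0.5]
        e0 = confidence_ellipse(pts, 95)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        e1 = confidence_ellipse(pts @ R.T, 95)
        dphi = (e1.phi - e0.phi - th + np.pi / 2) % np.pi - np.pi / 2
        assert abs(dphi) < 1e-6
        assert e1.a == pytest.approx(e0.a)

    def test_degenerate_cloud_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])  # collinear
        with pytest.raises(ValueError):
            confidence_ellipse(pts, 95)

    def test_membership_matches_boundary_equation(self):
        e = Ellipse((1.0, 2.0), 0.4, 0.2, 0.5)
        th = np.linspace(0, 2 * np.pi, 33)
        c, s = np.cos(e.phi), np.sin(e.phi)
        x = 0.999 * e.a * np.cos(th)
        y = 0.999 * e.b * np.sin(th)
        world = np.column_stack([x * c - y * s, x * s + y * c]) + [1.0, 2.0]
        assert e.contains(world).all()
        xo = 1.001 * e.a * np.cos(th)
        yo = 1.001 * e.b * np.sin(th)
        world_out = np.column_stack([xo * c - yo * s, xo * s + yo * c]) + [1.0, 2.0]
        assert not e.contains(world_out).any()


class TestOUMLE:
    def test_recovery_on_simulated_process(self):
        lam, D, dt = 10.0, 0.05, 0.01
        x = _ou_path(lam, D, dt, 10000, mu=0.3, seed=3)
        lhat, Dhat, _, muhat, ok = ou_mle_1d(x[:-1], x[1:], dt)
        assert ok
        assert lhat == pytest.approx(lam, rel=0.10)
        assert Dhat == pytest.approx(D, rel=0.05)
        assert muhat == pytest.approx(0.3, abs=0.02)

    def test_closed_form_matches_brute_force(self):
        # numerical maximization of the transition likelihood over
        # (mu, lambda, D) must agree with the closed form
        from scipy.optimize import minimize

        x = _ou_path(8.0, 0.08, 0.01, 50, seed=4)
        x0, x1 = x[:-1], x[1:]
        lhat, Dhat, _, muhat, ok = ou_mle_1d(x0, x1, 0.01)
        assert ok
        res = minimize(
            lambda p: -ou_loglik_1d(x0, x1, 0.01, p[0], p[1], np.exp(p[2])),
            [muhat + 0.05, lhat * 1.5, np.log(Dhat * 2)],
            method="Nelder-Mead",
            options=dict(xatol=1e-13, fatol=1e-13, maxiter=40000, maxfev=40000),
        )
        assert res.x[1] == pytest.approx(lhat, rel=1e-6)
        assert np.exp(res.x[2]) == pytest.approx(Dhat, rel=1e-6)

    def test_brownian_limit_gives_msd_estimator(self):
        rng = np.random.default_rng(5)
        dt, D = 0.01, 0.05
        steps = rng.normal(0, np.sqrt(2 * D * dt), 20000)
        x = np.cumsum(steps)
        lhat, Dhat, _, _, ok = ou_mle_1d(x[:-1], x[1:], dt)
        if ok:  # slope may fall on either side of 1
            msd_D = np.mean(np.diff(x) ** 2) / (2 * dt)
            assert Dhat == pytest.approx(msd_D, rel=0.02)

    def test_anti_persistent_sample_flagged(self):
        x0 = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        x1 = -x0
        *_, ok = ou_mle_1d(x0, x1, 0.1)
        assert not ok

    def test_2d_fit_rotates_into_frame(self):
        lam1, lam2, D, dt = 20.0, 5.0, 0.05, 0.01
        xa = _ou_path(lam1, D, dt, 8000, seed=6)
        xb = _ou_path(lam2, D, dt, 8000, seed=7)
        phi = 0.6
        c, s = np.cos(phi), np.sin(phi)
        R = np.array([[c, -s], [s, c]])
        pts = np.column_stack([xa, xb]) @ R.T
        fit = ou_mle(pts[:-1], pts[1:], dt, mu=(0.0, 0.0), phi=phi)
        assert fit.valid
        assert fit.lam[0] == pytest.approx(lam1, rel=0.1)
        assert fit.lam[1] == pytest.approx(lam2, rel=0.1)

    def test_moment_estimator_biased_low_under_confinement(self):
        # confined OU at coarse sampling: MSD saturates, so the moment
        # lambda underestimates while the MLE stays near truth
        lam, D, dt = 20.0, 0.05, 0.02
        xa = _ou_path(lam, D, dt, 20000, seed=8)
        xb = _ou_path(lam, D, dt, 20000, seed=9)
        pts = np.column_stack([xa, xb])
        fit = ou_mle(pts[:-1], pts[1:], dt, mu=(0.0, 0.0))
        lmom = moment_lambda(pts[:-1], pts[1:], dt, (0.0, 0.0))
        assert np.mean(lmom) < np.mean(fit.lam)
        assert abs(np.mean(fit.lam) - lam) < abs(np.mean(lmom) - lam)

    def test_brownian_loglik_is_ou_limit(self):
        x = _ou_path(5.0, 0.05, 0.01, 200, seed=10)
        D = np.mean(np.diff(x) ** 2) / (2 * 0.01)
        l0 = brownian_loglik_1d(x[:-1], x[1:], 0.01)
        l_eps = ou_loglik_1d(x[:-1], x[1:], 0.01, 0.0, 1e-9, D)
        assert l_eps == pytest.approx(l0, abs=1e-3)


class TestResidenceTime:
    def test_direct_evaluation(self):
        # r=0.1, A=0.3, D=0.1: D r^2/(4A^2) e^{A/D} = 0.001/0.36 * e^3
        tau = residence_time(0.1, 0.1, 0.3, 0.1)
        assert tau == pytest.approx(0.001 / 0.36 * np.exp(3.0), rel=1e-12)
        assert tau == pytest.approx(0.0558, abs=2e-4)

    def test_quadratic_scaling_in_radius(self):
        t1 = residence_time(0.1, 0.1, 0.3, 0.1)
        t2 = residence_time(0.2, 0.2, 0.3, 0.1)
        assert t2 == pytest.approx(4 * t1)

    def test_monotone_in_energy(self):
        taus = [residence_time(0.1, 0.1, e * 0.1, 0.1) for e in (3, 4, 5, 6)]
        assert np.all(np.diff(taus) > 0)

    def test_zero_attraction_undefined(self):
        assert residence_time(0.1, 0.1, 0.0, 0.1) is None


class TestParabolicIndex:
    def test_perfect_parabolic_field(self):
        rng = np.random.default_rng(11)
        xy = rng.uniform(-0.2, 0.2, (40, 2))
        A, a, b = 0.3, 0.25, 0.2
        drift = np.column_stack([-2 * A * xy[:, 0] / a**2, -2 * A * xy[:, 1] / b**2])
        Ahat, S = parabolic_index(xy, drift, a, b)
        assert Ahat == pytest.approx(A, rel=1e-9)
        assert S == pytest.approx(0.0, abs=1e-12)

    def test_random_field_scores_near_one(self):
        rng = np.random.default_rng(12)
        S_vals = []
        for _ in range(100):
            xy = rng.uniform(-0.2, 0.2, (30, 2))
            drift = rng.normal(size=(30, 2))
            _, S = parabolic_index(xy, drift, 0.25, 0.2)
            S_vals.append(S)
        assert np.mean(S_vals) >= 0.8
        assert np.all((np.asarray(S_vals) >= 0) & (np.asarray(S_vals) <= 1))
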