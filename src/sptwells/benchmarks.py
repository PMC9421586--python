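"""Validation studies run against the built-in simulators.

Each function simulates data under fixed, documented study conditions,
runs the corresponding estimator, and returns summary metrics.  These
studies back both the test suite and the reproduction script; sample sizes
are chosen so that each study finishes in well under a minute on one core
(the methods note lists the problem sizes).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .lyso import detect_confinements, fit_exponential_durations, fit_velocity_mixture
from .maps import cosine_filtered_maps, diffusion_map
from .netgraph import GRAParams, reconstruct_graph, suggest_velocity_threshold
from .simulate import (
    SimConfig,
    SyntheticGraph,
    WellSpec,
    first_exit_times,
    lattice_graph,
    simulate_on_graph,
    simulate_switching,
    simulate_well,
    triangle_graph,
    two_node_graph,
)
from .traj_core import TrajectoryEnsemble, ensemble_from_arrays
from .wells import (
    DensityParams,
    DriftParams,
    HybridParams,
    chi2_quantile,
    detect_wells_density,
    detect_wells_drift,
    detect_wells_hybrid,
    moment_lambda,
    ou_loglik_1d,
    ou_mle,
    ou_mle_1d,
    residence_time,
)

__all__ = [
    "WELL_BENCH",
    "ou_oracle_equivalence",
    "simulate_bench_well",
    "brownian_control",
    "well_recovery_study",
    "false_positive_study",
    "estimator_comparison",
    "moment_vs_mle_study",
    "cosine_filter_study",
    "residence_time_study",
    "gra_study",
    "confinement_study",
    "velocity_mixture_study",
]

# Reference well benchmark: a 150 nm isotropic well (D = 0.1 μm²/s) embedded
# in a 2×2 μm reflecting observation region, sampled as 300 trajectories of
# 40 points at 20 ms (12,000 points), mimicking dense SPT coverage with
# escape and recapture.
WELL_BENCH = dict(
    a=0.15,
    b=0.15,
    D=0.1,
    dt_obs=0.02,
    n_traj=300,
    traj_len=40,
    domain=(-1.0, -1.0, 1.0, 1.0),
    substeps=50,
)


def _spawn(seed: int, k: int) -> int:
    """Derive a child seed below 2^31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# OU maximum likelihood vs brute force


def ou_oracle_equivalence(seed: int = 0, n_instances: int = 100, n_pairs: int = 50) -> dict:
    """Closed-form OU MLE vs numerical maximization of the log-likelihood.

    Random 1-D OU instances are simulated exactly; the closed-form λ̂, D̂
    are compared with a Nelder-Mead maximization of the transition
    log-likelihood over (μ, λ, D) started away from the solution.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_done = 0
    while n_done < n_instances:
        lam = rng.uniform(2, 20)
        D = rng.uniform(0.01, 0.2)
        dt = 0.01
        mu = rng.uniform(-1, 1)
        th = np.exp(-lam * dt)
        sd = np.sqrt(D * (1 - th**2) / lam)
        x = np.empty(n_pairs + 1)
        x[0] = mu + rng.standard_normal() * np.sqrt(D / lam)
        for i in range(n_pairs):
            x[i + 1] = mu + (x[i] - mu) * th + sd * rng.standard_normal()
        x0, x1 = x[:-1], x[1:]
        lam_cf, D_cf, _, mu_cf, ok = ou_mle_1d(x0, x1, dt)
        if not ok:
            continue
        n_done += 1

        def nll(p):
            return -ou_loglik_1d(x0, x1, dt, p[0], p[1], np.exp(p[2]))

        res = minimize(
            nll,
            [mu_cf * 1.1 + 0.01, lam_cf * 1.2 + 0.5, np.log(D_cf * 1.3)],
            method="Nelder-Mead",
            options=dict(xatol=1e-13, fatol=1e-13, maxiter=40000, maxfev=40000),
        )
        lam_n, D_n = res.x[1], np.exp(res.x[2])
        err = max(abs(lam_n - lam_cf) / max(abs(lam_cf), 1e-9), abs(D_n - D_cf) / D_cf)
        worst = max(worst, err)
    return {"max_rel_err": worst, "n": n_instances}


# ---------------------------------------------------------------------------
# well benchmark helpers


def simulate_bench_well(energy: float, seed: int, **overrides) -> tuple[WellSpec, TrajectoryEnsemble]:
    b = {**WELL_BENCH, **overrides}
    spec = WellSpec((0.0, 0.0), b["a"], b["b"], 0.0, energy * b["D"], b["D"])
    cfg = SimConfig(
        dt_obs=b["dt_obs"],
        n_traj=b["n_traj"],
        traj_len=b["traj_len"],
        seed=seed,
        dt_sim=b["dt_obs"] / b["substeps"],
        domain=b["domain"],
    )
    return spec, simulate_well(spec, cfg)


def brownian_control(seed: int, **overrides) -> TrajectoryEnsemble:
    """Pure free Brownian motion at the benchmark sampling density (E = 0).

    Exact Gaussian increments (no integrator error), uniform starting
    positions over the benchmark region, no walls and no potential.
    """
    b = {**WELL_BENCH, **overrides}
    rng = np.random.default_rng(seed)
    lo = np.array(b["domain"][:2])
    hi = np.array(b["domain"][2:])
    sd = np.sqrt(2 * b["D"] * b["dt_obs"])
    paths = []
    for _ in range(b["n_traj"]):
        x0 = lo + rng.random(2) * (hi - lo)
        steps = rng.normal(0, sd, (b["traj_len"] - 1, 2))
        paths.append(np.vstack([x0, x0 + np.cumsum(steps, axis=0)]))
    return ensemble_from_arrays(paths, b["dt_obs"])


def _best_well(wells):
    return max(wells, key=lambda w: w.logL if np.isfinite(w.logL) else -np.inf)


def well_recovery_study(
    seed: int = 0,
    energies: tuple[int, ...] = tuple(range(1, 11)),
    n_seeds: int = 5,
) -> dict:
    """Hybrid-algorithm parameter recovery across well energies.

    For each energy and replicate, a benchmark well is simulated and the
    hybrid detector is run with default parameters.  Reported: detection
    rate for E ≥ 2 kT, median center error, and median energy error for
    true E ≤ 8 kT (pooled over detected wells).
    """
    det2 = n2 = 0
    center_errs = []
    e_errs_le8 = []
    per_energy = {}
    for E in energies:
        errs = []
        det = 0
        for r in range(n_seeds):
            spec, ens = simulate_bench_well(E, _spawn(seed, 1000 * E + r))
            found = detect_wells_hybrid(ens, HybridParams())
            if E >= 2:
                n2 += 1
            if not found:
                continue
            w = _best_well(found)
            det += 1
            if E >= 2:
                det2 += 1
            center_errs.append(float(np.hypot(*w.center)))
            errs.append(abs(w.energy - E))
            if E <= 8:
                e_errs_le8.append(abs(w.energy - E))
        per_energy[E] = {
            "detected": det,
            "median_energy_error": float(np.median(errs)) if errs else None,
        }
    return {
        "detection_rate_E2plus": det2 / n2,
        "median_center_error_nm": 1e3 * float(np.median(center_errs)),
        "median_energy_error_kT": float(np.median(e_errs_le8)),
        "per_energy": per_energy,
        "n_wells": n2,
    }


def false_positive_study(seed: int = 0, n_rep: int = 20) -> dict:
    """Hybrid detections on pure Brownian replicates (should be none)."""
    fp = 0
    for r in range(n_rep):
        ens = brownian_control(_spawn(seed, 77000 + r))
        if detect_wells_hybrid(ens, HybridParams()):
            fp += 1
    return {"false_positive_rate": fp / n_rep, "n": n_rep}


def estimator_comparison(
    seed: int = 0, energies: tuple[int, ...] = (2, 4, 6), n_seeds: int = 3
) -> dict:
    """Paired comparison of the three well-detection algorithms.

    On identical simulated wells, boundary error |â − a|/a and energy
    error |Ê − E| are averaged per algorithm over the replicates where
    that algorithm reports a well near the true center.
    """
    errs = {"hybrid": [], "density": [], "drift": []}
    bnd = {"hybrid": [], "density": [], "drift": []}
    for E in energies:
        for r in range(n_seeds):
            spec, ens = simulate_bench_well(E, _spawn(seed, 2000 * E + r))
            for name, det, params in (
                ("hybrid", detect_wells_hybrid, HybridParams()),
                ("density", detect_wells_density, DensityParams()),
                ("drift", detect_wells_drift, DriftParams()),
            ):
                found = [
                    w for w in det(ens, params) if np.hypot(*w.center) < 0.3
                ]
                if not found:
                    continue
                w = found[0]
                errs[name].append(abs(w.energy - E))
                bnd[name].append(abs(w.boundary.a - spec.a) / spec.a)
    return {
        "mean_energy_error": {k: float(np.mean(v)) if v else None for k, v in errs.items()},
        "mean_boundary_error": {k: float(np.mean(v)) if v else None for k, v in bnd.items()},
        "n_detected": {k: len(v) for k, v in errs.items()},
    }


def moment_vs_mle_study(seed: int = 0, energy: float = 4.0, n_seeds: int = 5) -> dict:
    """Spring-constant estimation: moment estimator vs MLE on the same wells.

    Both estimators run on the displacement pairs inside the true boundary
    with the true center supplied; the moment estimator is expected to be
    biased low because the mean squared displacement saturates under
    confinement.
    """
    lam_true = 2 * energy * WELL_BENCH["D"] / WELL_BENCH["a"] ** 2
    mle, mom = [], []
    for r in range(n_seeds):
        spec, ens = simulate_bench_well(energy, _spawn(seed, 30000 + r))
        disp = ens.displacements()
        p0 = disp.origins
        p1 = p0 + disp.dxy
        inside = spec.contains(p0) & spec.contains(p1)
        fit = ou_mle(p0[inside], p1[inside], ens.dt, mu=spec.center)
        lm = moment_lambda(p0[inside], p1[inside], ens.dt, spec.center)
        if fit.valid:
            mle.append(float(np.mean(fit.lam)))
        mom.append(float(np.mean(lm)))
    return {
        "lambda_true": lam_true,
        "lambda_mle_mean": float(np.mean(mle)),
        "lambda_moment_mean": float(np.mean(mom)),
    }


# ---------------------------------------------------------------------------
# cosine filtering


def cosine_filter_study(seed: int = 0, n_traj: int = 400, traj_len: int = 30) -> dict:
    """Plain vs cosine-filtered diffusion maps on a varying-D field.

    Brownian trajectories with D(x) = 0.05 + 0.0125·x μm²/s over a 4×4 μm
    region; both maps share Δx = 0.2 μm, the cosine filter uses r = 0.3 μm.
    Reports bin coverage and mean absolute error against the true field.
    """
    rng = np.random.default_rng(seed)
    paths = []
    for _ in range(n_traj):
        x = rng.random(2) * 4
        pts = [x.copy()]
        for _ in range(traj_len - 1):
            D = 0.05 + 0.0125 * np.clip(pts[-1][0], 0, 4)
            pts.append(pts[-1] + rng.normal(0, np.sqrt(2 * D * 0.02), 2))
        paths.append(np.array(pts))
    ens = ensemble_from_arrays(paths, 0.02)
    dx = 0.2
    plain = diffusion_map(ens, dx, min_disp=15)
    _, cosine = cosine_filtered_maps(ens, dx, r_filt=0.3, min_disp=15)

    def stats(m):
        cx, _ = m.grid.centers()
        X = cx[:, None] * np.ones((1, m.grid.ny))
        truth = 0.05 + 0.0125 * np.clip(X, 0, 4)
        ok = np.isfinite(m.values)
        return float(ok.mean()), float(np.abs(m.values - truth)[ok].mean())

    cov_p, mae_p = stats(plain)
    cov_c, mae_c = stats(cosine)
    return {
        "coverage_plain": cov_p,
        "coverage_cosine": cov_c,
        "mae_plain": mae_p,
        "mae_cosine": mae_c,
    }


# ---------------------------------------------------------------------------
# residence time


def residence_time_study(
    seed: int = 0, energies: tuple[int, ...] = (3, 4, 5), n: int = 600
) -> dict:
    """Escape-time formula vs Monte-Carlo mean first-exit time.

    Particles start at the well center; integration at 20 μs keeps the
    discretization bias of the exit detection small.
    """
    out = {}
    for E in energies:
        A = E * WELL_BENCH["D"]
        spec = WellSpec((0.0, 0.0), WELL_BENCH["a"], WELL_BENCH["b"], 0.0, A, WELL_BENCH["D"])
        tau = residence_time(spec.a, spec.b, A, spec.D)
        exits = first_exit_times(spec, n=n, seed=_spawn(seed, 40000 + E), dt_sim=2e-5, t_max=tau * 8)
        out[E] = {"formula": tau, "mc": float(exits.mean()), "n_exits": int(exits.size)}
    return out


# ---------------------------------------------------------------------------
# graph reconstruction


def gra_study(seed: int = 0) -> dict:
    """Edge recovery of the GRA on three synthetic networks.

    Two-node, triangle, and 2×5 lattice graphs (0.7 μm pitch, 0.25 μm node
    radius) with node dwell bias 6 and tubule D = 0.08 μm²/s; the velocity
    threshold is taken at the antimode of the speed distribution.  The
    error is (missing + spurious edges)/(true edges) pooled over graphs.
    """
    cases = (
        (two_node_graph(), 80, 250),
        (triangle_graph(), 120, 250),
        (lattice_graph(2, 5), 250, 250),
    )
    tot_m = tot_s = tot_T = 0
    details = []
    for k, (g, n_traj, traj_len) in enumerate(cases):
        cfg = SimConfig(
            dt_obs=0.05, n_traj=n_traj, traj_len=traj_len, seed=_spawn(seed, 50000 + k), dt_sim=0.005
        )
        ens = simulate_on_graph(g, D=0.08, node_dwell_bias=6.0, cfg=cfg)
        v_th = suggest_velocity_threshold(ens.displacements().speeds)
        rec = reconstruct_graph(ens, GRAParams(v_th=v_th))
        miss, spur, T = _edge_error(g, rec)
        tot_m += miss
        tot_s += spur
        tot_T += T
        details.append(
            {"nodes": len(rec.nodes), "true_nodes": len(g.nodes), "missing": miss, "spurious": spur}
        )
    return {
        "edge_error_pct": 100.0 * (tot_m + tot_s) / tot_T,
        "true_edges": tot_T,
        "details": details,
    }


def _edge_error(true_graph: SyntheticGraph, rec) -> tuple[int, int, int]:
    true_edges = {(min(i, j), max(i, j)) for i, j in true_graph.edges}
    if not rec.nodes:
        return len(true_edges), 0, len(true_edges)
    centers = np.array([n.center for n in rec.nodes])
    mapping = {
        i: int(np.argmin(np.hypot(*(true_graph.nodes - c).T))) for i, c in enumerate(centers)
    }
    rec_edges = {
        (min(mapping[i], mapping[j]), max(mapping[i], mapping[j]))
        for i, j in rec.edges
        if mapping[i] != mapping[j]
    }
    return len(true_edges - rec_edges), len(rec_edges - true_edges), len(true_edges)


# ---------------------------------------------------------------------------
# confinement and velocity mixture


def confinement_study(seed: int = 0, n_traj: int = 60, traj_len: int = 1200) -> dict:
    """Transient-confinement detection on two-state switching motion.

    True confined dwell time 1/rate_off = 5 s; the detected confinement
    durations are fitted by a left-truncated exponential (truncation at the
    minimal detectable window N_nh·Δt).
    """
    ou = WellSpec((0, 0), 0.05, 0.05, 0.0, 0.0125, 0.01)  # λ = 10 s⁻¹, D = 0.01
    cfg = SimConfig(dt_obs=0.1, n_traj=n_traj, traj_len=traj_len, seed=_spawn(seed, 60000), dt_sim=0.1)
    ens, truth = simulate_switching(v_fast=1.0, ou=ou, rate_on=0.5, rate_off=0.2, cfg=cfg)
    events = detect_confinements(ens, n_nh=10, r_nh=0.3)
    durations = np.array([ev.duration for ev in events])
    tau_hat = fit_exponential_durations(durations, t_min=10 * cfg.dt_obs)
    return {
        "tau_true": 5.0,
        "tau_hat": tau_hat,
        "n_events": len(events),
        "n_true_dwells": int(truth["confined_dwells"].size),
    }


def velocity_mixture_study(seed: int = 0, n: int = 100_000) -> dict:
    """Two-exponential recovery on synthetic speeds (v₀=0.05, v₁=0.4, 10:1)."""
    rng = np.random.default_rng(seed)
    slow = rng.random(n) < 10 / 11
    speeds = np.where(slow, rng.exponential(0.05, n), rng.exponential(0.4, n))
    fit = fit_velocity_mixture(speeds)
    return {
        "v0_true": 0.05,
        "v1_true": 0.4,
        "v0": fit.v0,
        "v1": fit.v1,
        "r2": fit.r2,
        "n": n,
    }


def psi_quantiles() -> dict:
    """Confidence-ellipse χ² scale factors at 90/95/99%."""
    return {"psi90": chi2_quantile(90), "psi95": chi2_quantile(95), "psi99": chi2_quantile(99)}
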