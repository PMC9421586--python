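# sptwells

High-throughput analysis of 2-D single-particle trajectories (SPTs):
local density, drift, and diffusion mapping; detection and
parameterization of high-density nanodomains as attracting potential
wells; sliding-window well stability; graph reconstruction of organelle
networks (e.g. the endoplasmic reticulum) explored by trajectories; and
mixed-motion analyses for lysosome-like organelles (velocity mixtures,
high-density regions, transient confinement). A built-in Langevin
simulator provides ground truth for every estimator.

It is written for cell biologists and biophysicists who have trajectory
tables (plain CSV or TrackMate spot exports) from sptPALM / uPAINT /
organelle-tracking experiments and want quantitative maps and nanodomain
parameters rather than images.

## The model

Trajectories are modeled by the overdamped Langevin equation

    dX = a(X) dt + √(2D(X)) dW,

whose drift field `a(X)` and diffusion tensor `D(X)` are estimated per
square bin of width Δx from conditional displacement moments

    a(x_k)   ≈ ⟨ΔX⟩ / Δt,         D^(u,v)(x_k) ≈ ⟨ΔX_u ΔX_v⟩ / (2Δt),

optionally refined by cosine-weighted moving disks (weight
cos(π/2·d/r)), which raises bin coverage and lowers the map error.

A nanodomain is a truncated elliptic parabolic well

    U(X) = A[(x'/a)² + (y'/b)² − 1]   inside the boundary ellipse, 0 outside,

so that in-well motion is an Ornstein–Uhlenbeck (OU) process with spring
constants λ⁽¹⁾ = 2A/a², λ⁽²⁾ = 2A/b². Each well is characterized by its
boundary ellipse (μ, a, b, φ), attraction A (μm²/s), diffusion D (μm²/s),
energy E = A/D (kT), and Kramers-type residence time
τ_e = D r²/(4A²)·e^{A/D} with r = √(ab). λ and D are estimated by the
exact discrete-time OU maximum likelihood; three detection algorithms
(hybrid density-drift, density-based, drift-based) locate wells from
high-density seeds and estimate their boundaries.

Networks are reconstructed by clustering low-speed trajectory points with
recursive DBSCAN into nodes and linking nodes traversed by a trajectory
within one or two frames (the GRA).

## Worked example

Simulate a 4 kT well (a = b = 150 nm, D = 0.1 μm²/s) embedded in a 2×2 μm
observation region and recover it:

```python
from sptwells import (SimConfig, WellSpec, simulate_well,
                      detect_wells_hybrid, HybridParams)

spec = WellSpec(center=(0.0, 0.0), a=0.15, b=0.15, A=0.4, D=0.1)  # E = 4 kT
cfg = SimConfig(dt_obs=0.02, n_traj=300, traj_len=40, seed=11,
                dt_sim=0.02 / 50, domain=(-1, -1, 1, 1))
ens = simulate_well(spec, cfg)

(w,) = detect_wells_hybrid(ens, HybridParams())
print(f"center=({w.center[0]:.4f}, {w.center[1]:.4f}) um  "
      f"a={w.boundary.a*1e3:.0f} nm  b={w.boundary.b*1e3:.0f} nm")
print(f"A={w.A:.3f} um^2/s  D={w.D:.3f} um^2/s  E={w.energy:.2f} kT  "
      f"tau_e={w.tau_e:.2f} s")
```

Output:

```
center=(-0.0085, 0.0050) um  a=188 nm  b=158 nm
A=0.427 um^2/s  D=0.108 um^2/s  E=3.94 kT  tau_e=0.23 s
```

The detected center is within 10 nm of the true one, the boundary
(188 × 158 nm) brackets the true 150 nm well, the energy estimate
3.94 kT is within the ±1 kT band the detector achieves on this
benchmark, and τ_e is the mean residence time implied by the fitted
parameters.

The same analyses run from the shell on any trajectory CSV
(`traj, frame|t, x, y` columns):

```bash
sptwells simulate --config sim.yaml --seed 1 --out data/
sptwells wells --config run.yaml --algo hybrid --out results/
sptwells graph --config run.yaml --out results/
sptwells run   --config run.yaml --seed 1 --out results/
```

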