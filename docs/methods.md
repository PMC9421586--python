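# Methods

This note documents the models, estimators, and numerical choices behind
`sptwells`, and what the built-in validation studies do and do not show.

## Trajectory model and units

All analyses operate on an ensemble of short 2-D trajectories sharing one
acquisition interval Δt. Internally, positions are micrometres and times
seconds; readers convert nanometre coordinates and frame indices on
input. Missed frames break a trajectory into fragments (blinking is not
bridged — how broken tracks should be handled is not standardized, and
splitting is the conservative choice since every estimator here assumes
consecutive pairs one Δt apart); single-point fragments are dropped with
a logged count.

## Maps

Density, drift, and diffusion are estimated per square half-open bin
[x, x+Δx)×[y, y+Δx), with the grid anchored at the lower-left corner of
the data bounding box (anchoring is arbitrary; half-open bins resolve
boundary ties). Each displacement is assigned to the bin of its origin
point. Defaults: Δx = 80 nm and a 15-displacement minimum per bin for
drift/diffusion, 50 nm bins with 3×3 Gaussian smoothing for density —
values typical of dense sptPALM data, all configurable. Bins below the
minimum count are reported missing (NaN), never zero.

The d×d density smoother is a Gaussian kernel with σ = d/3 bins,
renormalized to unit sum; kernels clipped at the grid edge are
renormalized per source bin so total mass Σρ·Δx² stays equal to the point
count.

Cosine filtering replaces the square bin by a disk of radius r (default
100 nm) around each (optionally refined) bin center and weights each
displacement by cos(π/2·d/r) of its origin distance d. The weight is 1 at
the center and falls continuously to 0 at the disk edge, so neighbouring
estimates vary smoothly. The refinement factor for the fine grid
(Δx′ = Δx/l_sc) defaults to l_sc = 2; nothing in the estimator constrains
it, and 2 doubles resolution without emptying the disks.

## Ornstein–Uhlenbeck maximum likelihood

Inside a parabolic well the sampled motion is an exact AR(1) process:
x_{t+Δt} | x_t ~ N(μ + (x_t−μ)e^{−λΔt}, s) with s = D(1−e^{−2λΔt})/λ.
The MLE of e^{−λΔt} is the regression slope of x_{t+Δt} on x_t (sample
covariance over variance); μ is profiled from the intercept when not
supplied; D follows from the mean squared residual via the expression for
s. The λ→0 limit reproduces the free-diffusion estimator
D = ⟨Δx²⟩/(2Δt) per axis. Samples with a non-positive slope
(anti-persistent) are flagged invalid. In 2-D the fit is applied per axis
in the frame of the boundary ellipse. The closed form agrees with
numerical maximization of the transition log-likelihood to better than
1e-6 relative error (validated on random instances in the test suite).

A moment-based alternative (λ = D̂_MSD/Var with D̂_MSD = ⟨‖ΔX‖²⟩/(4Δt))
is provided for comparison; it is biased low under confinement because
the MSD saturates at finite Δt, which the validation study demonstrates.

## Potential wells

A well is a truncated elliptic parabola U(X) = A[(x'/a)² + (y'/b)² − 1]
inside its boundary ellipse and 0 outside; energy E = A/D in kT;
residence time τ_e = D r²/(4A²)e^{A/D} with r = √(ab) (a circular-well
approximation, accurate for a ≈ b; the Monte-Carlo study shows it
underestimates the simulated mean first-exit time by roughly 20–25 % at
E = 3–5 kT, inside the stated 30 % band).

### Detection

All three algorithms seed at the top d % (default 1 %) densest bins of a
coarse grid, with adjacent seed bins collapsed to their densest member.

**Hybrid density-drift.** Square neighbourhoods of side (2k+1)Δx grow
around each seed, re-centered each iteration at the enclosed center of
mass; the ellPerc (default 95 %) confidence ellipse ε_k is fitted from
the covariance of the enclosed points (semi-axes √(ψ·eigenvalue), ψ the
χ²₂ quantile), and λ, D are fitted by the OU MLE on the displacement
pairs originating inside ε_k, giving A_k = mean(λ⁽¹⁾a², λ⁽²⁾b²)/2 (the
two axes estimate A independently; averaging is the natural combination
for a single scalar A). The retained iteration is the first local maximum
of the per-ring OU log-likelihood (pairs in ε_k∖ε_{k−1}, rings with fewer
than ringMinPts trajectories skipped). Two deliberate choices here:

* the ring score is normalized per pair. The raw sum grows with ring
  occupancy, so in any populated field the curve keeps rising and the
  termination overshoots; the per-pair score is comparable across rings.
* among iterations up to the selected one, the final candidate is the
  largest neighbourhood whose OU-evidence density (log-likelihood ratio
  against pure diffusion, per pair) stays within 60 % of the peak. The
  evidence density peaks when the ellipse matches the actual basin;
  without this rule shallow wells (≲3 kT) terminate on background-scale
  ellipses.

The multiscale variant repeats the search over a Δx grid and keeps, among
overlapping detections, the one with the highest in-ellipse likelihood.

**Screening.** A candidate becomes a well only if: both spring constants
are positive; the OU-versus-Brownian log-likelihood ratio inside the
boundary is at least llr_min (default 13, calibrated on free-Brownian
null simulations so that the false-positive rate is below 5 % per
dataset; true wells at these sampling densities score hundreds); the
boundary lies entirely inside the observed region (a basin cut by the
field of view cannot be parameterized, and reflection or loss at the
border mimics attraction); b ≥ 40 nm; and 0 < E ≤ 10 kT (deep-well
estimates beyond 10 kT are unreliable and conventionally filtered).
Overlapping detections from different seeds keep the highest-likelihood
one.

**Density-based.** The center is refined as the mean of level-set
centers over an α grid (default 0.3–0.8) on a 20 nm local grid; annuli of
width Δr = 20 nm are scanned outward; the axis ratio κ of annulus
confidence ellipses (for r < 300 nm) defines an ellipticity-corrected
radius, and the boundary is the first annulus where the corrected radial
density stops decreasing. D comes from the OU MLE inside the boundary and
A from the stationary covariance relation A = (D/2)(a²/σ₁₁ + b²/σ₂₂).

**Drift-based.** The same growing squares, but each iteration projects a
local drift map onto the parabolic template a(X) = −2A(x'/a², y'/b²) by
least squares; the parabolic index S_k ∈ [0,1] (residual fraction; 0 for
a perfect parabolic field, ≈1 for random drift) is minimized over
iterations. D is the local MSD estimator inside the final ellipse.
Candidates with S above 0.8 are rejected.

### What the validation shows

The well benchmark is a 150 nm isotropic well with D = 0.1 μm²/s embedded
in a 2×2 μm reflecting region, sampled as 300 trajectories × 40 points at
Δt = 20 ms (12,000 points), Euler–Maruyama integration at Δt/50.
Embedding the well in a bounded, uniformly seeded region reproduces the
escape/recapture background of real recordings; this matters because the
boundary of a deep well is otherwise unidentifiable — a purely in-well
equilibrium cloud is Gaussian, its ψ-scaled covariance ellipse shrinks
like 1/√E relative to the true boundary, and the reported energy
saturates near ψ/2 regardless of the true depth. With the background, the
detector recovers E to a pooled median error of ~0.6 kT over 1–8 kT
(per-energy medians are ≤1 kT up to 7 kT and ~1.2–1.3 kT at 8 kT, where
the 95 % cloud ellipse still slightly under-covers the boundary), centers
to a few nm, and flags nothing on free-Brownian controls. Passing these
studies shows the estimators are correct under the model's own
assumptions — isotropic diffusion, parabolic basins, no localization
noise; it does not certify performance on real data with localization
error, blinking, or non-parabolic confinement. Localization noise can be
added in the simulator (`loc_noise`) but defaults to 0.

The E = 0 control is free Brownian motion at matched sampling density.
Brownian motion confined by reflecting walls is *not* used as the control:
wall reflection produces genuine mean reversion at the wall scale, and
discriminating walls from wells is possible only when the observed region
is much larger than the candidate well.

## Time-lapse stability

Recordings are clipped into non-overlapping windows (default 20 s); wells
detected in consecutive windows are the same if their centers are within
200 nm. Matching is greedy by increasing distance, so the result does not
depend on list order; when two wells compete for one track the nearer one
wins and the other starts a new track (the convention is not otherwise
specified anywhere authoritative). A track missing for up to one window
(configurable) may be bridged; the stability duration τ = t_r − t_q is
reported from window start times, and bridged windows are recorded so
both lifetime conventions (with and without gap windows as presence) can
be computed downstream.

## Graph reconstruction (GRA)

Slow points (speed ≤ v_th) are clustered by DBSCAN with the loosest
(R, N) pair; clusters above maxClustNpts (default 1000) are recursively
re-clustered with stricter pairs (R descending, N ascending, the shorter
ladder cycling). Default ladders R = (0.15, 0.10, 0.06) μm,
N = (10, 20, 40): the loosest eps must stay below the node-to-node gap or
DBSCAN chains adjacent nodes through sparse slow points in tubules, and
the strictest rung must push the required local density above the tubule
level. Cluster boundaries default to convex hulls — confidence ellipses
overestimate cluster extent by the √ψ factor and cause spurious merges of
adjacent nodes; both modes are available. Discarded fast points inside a
boundary join that node; overlapping boundaries merge iteratively.
Connectivity counts first-order (consecutive points in two nodes) and
second-order (one off-node point in between) traversals; the matrix is
symmetrized (C + Cᵀ), with directional counts retained.

v_th defaults to Otsu's threshold on the speed histogram (the threshold
minimizing intra-class variance). An antimode (histogram valley) was
considered but is fragile when the slow and fast speed modes overlap
heavily, as they do for node/tubule diffusion contrasts of ~5×.

The synthetic networks (two-node, triangle, 2×5 lattice) use 0.25 μm node
disks, 0.7 μm pitch, 0.15 μm wide tubules, tubule D = 0.08 μm²/s, and a
6× slower in-node diffusion (the dwell bias that concentrates points in
nodes). The geometry is chosen so that the 0.2 μm inter-boundary gap is
crossable within the two-frame connectivity horizon at Δt = 50 ms; with
dwell bias 1 there is no density contrast and reconstruction is expected
to fragment. Edge recovery is exact on all three benchmarks across seeds;
this shows the recursion, merging, and connectivity logic are sound, not
that the defaults fit any particular organelle dataset — R, N, and v_th
are per-dataset choices.

Resynchronization re-origins trajectories at their first exit from a
chosen node (first point outside after ≥3 consecutive points inside, to
suppress boundary jitter) and reports the mean distance from the exit
point versus lag, plus per-event exit speeds. For free diffusion the
curve follows √(πDτ), which the tests verify.

## Mixed-motion analyses

**Velocity mixture.** f(v) = A·e^{−v/v₀} + B·e^{−v/v₁} is fitted by
nonlinear least squares to the density-normalized speed histogram
(60 bins by default — automatic fine binning leaves the sparse fast tail
so noisy that the fast scale biases low), initialized from the lower/upper
half-sample means. Non-convergence falls back to a single exponential and
is flagged.

**High-density regions.** Coarse 480 nm density map → top 5 % bins with
non-maximum suppression within two squares → per kept bin a 5×5 refined
map at 200 nm → points above 80 % of the local maximum → 95 % confidence
ellipse → iterative merging of overlapping ellipses. The top-percentile
threshold is taken over the whole map including empty bins, so isolated
hot spots in sparse fields all survive. The inter-HDR network links
regions traversed within one or two frames and fits a Rayleigh
distribution (maximum likelihood scale) to the traversal speeds with a
Kolmogorov–Smirnov adequacy check.

**Transient confinement.** From each start index, the successor window
grows while every member stays within R_nh (default 300 nm) of the
running center of mass; windows of at least N_nh (default 10) successors
become events; overlapping candidates collapse to the earliest-start
maximal event, and reaching the trajectory end closes the event there.
Each event gets a 95 % ellipse and per-axis OU parameters about the event
center of mass. Detected durations are left-truncated at N_nh·Δt, so the
exponential time constant is estimated as mean(duration) − N_nh·Δt
(memorylessness). The switching benchmark (ballistic runs at 1 μm/s
alternating with OU confinement, λ = 10 s⁻¹, D = 0.01 μm²/s, mean
confined dwell 5 s, 60 trajectories × 120 s at Δt = 0.1 s) recovers the
dwell constant to ~15 %; the residual bias is censoring of long dwells at
trajectory ends, which affects truth and detection alike.

## Pipeline

The CLI is a thin layer over the library: YAML configs are
schema-validated (unknown keys rejected), every run writes its resolved
configuration next to the outputs, and a fixed seed makes reruns
byte-identical. Stages run in the order maps → wells → timelapse → graph
→ lyso; a stage failure halts the run with the stage named in the error.

## Known limitations

* 2-D only; no localization-noise deconvolution (noise inflates D̂ and
  shrinks λ̂ at short Δt).
* The residence-time formula assumes a ≈ b; for elongated wells the
  harmonic-mean radius is reported without correction.
* Energy estimates above ~8 kT are boundary-limited (see above) and
  capped at 10 kT by the screening filter.
* The GRA assumes slow-in-node, fast-in-tubule contrast; uniform mobility
  fragments the reconstruction.
* Confinement detection reports biased dwell constants when trajectories
  are shorter than a few dwell times.
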