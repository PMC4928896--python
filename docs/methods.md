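# Methods

## Model

Cell density ρ(r,t), nutrient N(r,t) and EPS e(r,t) evolve on an annular
domain [r0, rb] outside the inoculum spot:

- **Motility.** Coarse-grained over many reversal periods, run-and-reverse
  gliding is diffusion with coefficient D(e) = D0 + Dp·φ(e). The basal
  coefficient D0 covers S-motility-independent spreading (growth-driven
  pushing); Dp is the ceiling set by pilus-driven movement, estimated from
  single-cell statistics by the velocity-jump relation Dp ≈ vg²/(2f)
  (80–245 µm²/min for vg = 4–7 µm/min, f = 0.1 /min). The gate
  φ(e) = eᵐ/(e0ᵐ+eᵐ) is a phenomenological Hill function read as the
  probability that a retraction finds EPS to pull against; m ≥ 4 is needed
  for the observed sharp density threshold (see the Hill study below).
- **Growth.** Monod kinetics g(N) = gmax·N/(N0+N); nutrient is consumed
  1:1, so the nutrient unit equals the (arbitrary) density unit and the
  wave amplitude is ≈ Nin. Default gmax = ln2 / (4 h).
- **EPS.** Produced at α per unit density, decays ("dries") at β; e0 is
  absorbed into α by rescaling (e0 = 1). The local steady state is
  e* = αρ/β, so the gating threshold in density units is ρ* = e0·β/α
  (≈ 0.84 for the soft-agar set).

Canonical units are µm and min; configs accept per-hour rates and convert
on load. Parameter sets shipped as configs: soft agar
(`soft_agar.yaml`: D0=2, Dp=220, DN=1e4 µm²/min, m=4, α=19/h, β=16/h,
g=0.173/h, N0=0.1, Nin=3, c0=0.003/µm), hard agar (`hard_agar.yaml`: g=0.154/h,
Dp=16, α=150/h) and the long-term soft-agar assay (`long_term_assay.yaml`: Dp=200).

## Boundary and initial conditions

The domain starts empty (ρ = e = 0, N = Nin). Cells enter at r0 with flux
D(e_spot(t))·c0·ρ_edge, where c0 = 0.003 /µm (10 % of 2f/vg) and
e_spot(t) = (α·ρ_edge/β)(1 − e^(−βt)) is the EPS the spot itself has
accumulated by time t. Gating the efflux by the *spot's* EPS — rather than
by the (initially zero) EPS just outside — is this package's reading of
the dispersal boundary condition: a dense inoculum switches its own
S motility on within minutes and exports cells at near the saturated flux
≈ 0.1·vg·ρ_edge, while a sparse one leaks at the basal flux for hours.
This choice is what produces lag saturation at high inoculum density
together with influx-limited, tens-of-hours lags at low density; without
it either every density lags or none does. ρ at rb and N, e at both ends
are no-flux.

**Inoculum density scale.** The model's density unit is arbitrary (tied
1:1 to the nutrient unit). Assay cell counts are converted to simulation
units as areal density in monolayer-equivalents:
ρ_edge = cells / (π·r0²·0.35 cells/µm²), with 0.35 cells/µm² a confluent
monolayer (≈ 4 × 0.7 µm footprint). This anchors the assay ladder
(6×10⁴–1.2×10⁷ cells per 1.7-mm spot → 0.019–3.8 units) across the EPS
gating threshold ρ* ≈ 0.84, which is the regime where the observed
hour-scale density-dependent lags occur. The literal "cells ÷ radius"
bookkeeping recipe is also provided (`conversion="radius"`), but it
produces values (35–7000) far above any gating threshold and should be
treated as a labeling convention, not a physical density.

## Numerical scheme

Vertex-centred finite volumes on a uniform grid (spacing dx, faces at
mid-nodes, exact discrete conservation; face diffusivity is the arithmetic
mean of node values), Crank-Nicolson for both diffusion operators. Each
step of size dt:

1. e is updated exactly over dt (linear ODE, ρ frozen);
2. ρ and N take CN diffusion solves (one tridiagonal system each); D(e) is
   evaluated at the updated EPS field and lagged within the step, so no
   Picard iteration is needed;
3. growth/consumption is applied explicitly with the post-diffusion N,
   capped at the available nutrient so N ≥ 0 and the ρ+N bookkeeping is
   exact to round-off.

CN undershoots by O(10⁻¹⁰·max ρ) ahead of the sharp front; values in
(−10⁻⁸·scale, 0) are clipped to zero and anything lower raises an error.
An accuracy guard warns when max(D)·dt/dx² > 50. Defaults dx = 30 µm,
dt = 0.05 min are conservative; the studies use dx = 20–25 µm and
dt = 0.5–1.5 min, at which halving both moves the measured front speed by
< 2 % (this convergence check is itself a test).

With the 1:1 conversion the traveling front connects ρ ≈ Nin (behind) to 0
(ahead); the front width is measured between the outermost crossings of
0.1·Nin and 0.9·Nin. The global density maximum sits at the r0 boundary,
where the constant influx piles cells up — that buildup is part of the
inoculum, not of the traveling wave. With DN = 10⁴ the width also carries
the slow √(DN·t) transient (≈ +0.3 % per 4 h at 150 h), so shape constancy
is judged between consecutive equidistant late snapshots, with the
window-wide spread reported alongside.

## Phase-space wave speed

Slaving e to e* = αρ/β reduces the model to (ρ, N). In the co-moving
coordinate z = x − ct, with the integration constant fixed by the
unpopulated state ahead, the profile solves a first-order autonomous
system; a front is a heteroclinic orbit from the saddle (Nin, 0) to the
node (0, Nin). The solver shoots from 10⁻⁶·Nin along the saddle's unstable
eigendirection (LSODA, rtol 10⁻⁸, atol 10⁻¹²) and labels the orbit
oscillatory / negative / non-negative; the selected speed is the minimal
non-negative c, bisected to 10⁻³·c_max from the bracket
[c_min/2, 2·c_max], where c_min and c_max are the constant-diffusion
closed forms at D0 and D0+Dp. The oscillatory label uses the node
eigenvalue criterion (complex ⇔ c < c_min, since the node linearisation
only feels D(0) = D0); near the transition the spiral amplitude decays
below any integration tolerance, so sign-counting alone would bias the
bisection low. Sign changes along the orbit remain as a cross-check.

**Scope: DN = 0 only.** With diffusing nutrients the co-moving system
gains an auxiliary variable Ω = dN/dz and the leading-edge fixed point
(0, Nin, 0) acquires a *two*-dimensional unstable manifold; forward-shot
orbits escape along the slow nutrient mode at every speed (the escape-flip
near 2.4 µm/min is a nutrient-diffusion scale, independent of Dp, and far
from the PDE front speed). The non-negativity selection criterion is
therefore only meaningful in the DN = 0 reduction, and
`wave_speed_phase_space` refuses DN > 0; front speeds with diffusing
nutrients are measured from the PDE. In the PDE, nutrient diffusion
*lowers* the finite-time front speed (0.92 vs 0.99 µm/min at Dp = 220;
0.18 vs 0.29 at Dp = 16): the colony is a nutrient sink and the depletion
layer ahead of the front grows like √(DN·t), so the speed deviates from
the √Dp scaling most strongly for slow (small-Dp) waves and drifts on the
measurement horizon. This is also why the lag study below switches DN off.

## Front analytics

The front is the outermost radius where ρ crosses ρ* = 0.01 (linearly
interpolated); the expansion rate is its finite-difference derivative.
The steady speed is the least-squares slope over the trailing 20 % of the
trajectory. "Lag" has no standard quantitative definition; here it is the
earliest time the (3-point-smoothed) rate first exceeds 50 % of the steady
speed, both fractions configurable. Front sampling every ≥ 2 h keeps the
interpolation quantization (≈ dx/2 per sample) small against the per-interval
advance.

## Calibration and the synthetic assay

The synthetic assay mirrors the published protocol: spots of
6×10⁴–1.2×10⁷ cells (2×10⁷–4×10⁹ cells/ml × 3 µl) at r0 = 1700 µm, radii
read at 2, 4, 6, 8 h then every 12 h to 96 h, with additive zero-mean
Gaussian measurement error of σ = 100 µm (the scale of circle-fitting
error on a stereo-microscope image), reproducible from a seed. It emulates
radius trajectories only — no imaging artefacts, no replicate structure,
no strain-to-strain variation — so passing recovery tests demonstrate that
the fitting machinery works when the model is correct, not that the model
fits any particular real dataset.

Fitting minimises (optionally inverse-variance-weighted) SSE of radii over
a free subset of {Dp, α, m}: a log-spaced coarse grid (4–5 points per
axis) seeds Nelder-Mead in log space; one forward simulation per unique
density per evaluation. Identifiability: a single late endpoint cannot
separate Dp from α (a 1.5× error in Dp is absorbed exactly by a wrong α);
time-course data breaks the degeneracy through the lag, and {Dp, α} are
recovered within 20 % from σ = 100 µm data (worst of three seeds).

## Study problem sizes

Chosen so each study resolves what it measures: wave emergence 150 h on
the full 30-mm domain (dx 20 µm, dt 0.5 min, DN = 10⁴); PDE/phase-space
comparison at DN = 0 on 12 mm (the Dp = 0 control at dx 10 µm — that front
is only D0/c ≈ 15 µm wide); lag ladder 120 h on 10 mm at DN = 0; Hill and
recovery studies on 2.6–3.6-mm domains at dx 25 µm, dt 1.5 min with 24-h
endpoint / 48-h course data. The radial curvature term decays with 1/r, so
phase-space (planar) speeds sit ~2 % above PDE speeds measured at r ≲ 10 mm;
this offset is part of the 5 % comparison band, not a bug.

## Known limitations

- The model is radially symmetric: no fingering, rafts or flares, which
  real S-motile colonies display at their edges.
- φ(e) is phenomenological; no pilus-level mechanics.
- The inoculum interior is not modelled; it acts only through the gated
  edge flux, and ρ_edge's absolute scale rests on the monolayer anchor
  above.
- Front speeds with DN > 0 are horizon-dependent (slow √t depletion
  transient); quote them with the measurement time.
- The fit explores {Dp, α, m} only; D0, β, N0, c0 are taken as known.
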