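# Methods

## Scope and model structure

`mtseq` models the spatial regulation of microtubule-binding molecules at
two levels of description that share one kinetic parameterization:

1. an **agent-based Brownian-dynamics engine** that traces individual,
   non-interacting motor/cargo particles through explicit 3D microtubule
   arrays (bipolar spindles, single asters, growing centrosome pairs); and
2. a **mean-field reaction–diffusion solver** for the free and bound
   concentration fields on a cortical block subdivided into energids, used
   for photobleaching protocols where tracing single molecules would be
   wasteful.

A 2D periodic-box **calibration** connects the two: it converts a
microtubule areal density and particle size into the effective binding rate
the mean-field tier uses.

## Agent tier

### Update rule

Particles carry a position, a binary state (free/bound), and — when bound —
a host filament and an arc-length coordinate measured from the minus end.
Per time step Δt (default 10⁻⁴ s), in order:

* **Free:** add an isotropic Gaussian displacement with per-axis variance
  2·D_C·Δt; reflect specularly at the cell sphere; then bind with
  probability 1 to the nearest filament whose axis lies within
  R_M + r + d₀ of the particle centre (ties: smaller gap, then lower
  filament id).  Binding snaps the particle onto the axis point at the
  clamped orthogonal projection; the radial offset is not tracked.
* **Bound:** unbind with probability 1 − exp(−k·Δt), releasing the particle
  at its current axis point (it resumes diffusion the next step, and may
  rebind immediately — rapid rebinding near the poles is what makes pole
  accumulation nearly leak-free).  Otherwise advance the arc coordinate by
  sign·V·Δt + √(2·D_M·Δt)·η, with sign −1 for dynein (toward the pole), +1
  for kinesin, 0 for a motor-free binder.  The minus end reflects
  (arc ← −arc), modelling a pole that expels arrivals instead of absorbing
  them; the plus end detaches by default (`plus_end_policy="reflect"` is
  available).  Bent filaments (barrel midzone) are chains of segments; a
  walker crossing a joint carries its arc coordinate onto the linked
  segment.

The binding probability upon proximity is 1 per step — the encounter is
treated as diffusion-limited, with d₀ (≈ a Debye length) the only
binding-range parameter.  No tunneling correction is applied: at the default
Δt the RMS free step (≈28 nm) is comparable to the binding cross-section
(18.3 nm), which is precisely the discretization at which the calibration
tier's k_on ≈ 5 s⁻¹ at 3 filaments/µm² was obtained, so Δt is part of the
model parameterization.  Enlarging Δt triggers a warning.

### Randomness and determinism

All stochastic draws come from a counter-based splitmix64 generator keyed on
(seed, particle id, global step, draw index).  Trajectories are therefore
bitwise reproducible for a fixed (geometry, parameters, seed) triple and
independent of particle iteration order; snapshots hash identically across
repeated runs.

### Proximity queries

Filament segments are rasterized once per geometry into a uniform spatial
hash (cell size 0.25 µm, exact Amanatides–Woo voxel traversal, CSR layout).
A binding query scans the 27 cells around the particle; because the cell
size exceeds the binding threshold, the query provably agrees with
brute-force nearest-segment search whenever the true distance is within one
cell size — the regime that matters for binding.  The contract is tested
against the brute-force kernel on random instances.

### Geometry

Spindles: two poles 10 µm apart in a 10 µm-radius cell; each pole nucleates
filaments on a 1 µm sphere, uniformly over solid angle — N_s = 800 inside
the 45°-half-angle cone opening toward the mid-plane (the "90° cone",
~14.6% of the sphere) and N_a = 800 outside it.  Plus ends stop at the
mid-cell plane or the cortex, whichever the nucleation ray reaches first.
Asters are isotropic with either full span (to the cortex) or a fixed
length, optionally clipped at the equator plane for half-cell arrays.

The **barrel midzone** variant bends each cone filament where it would cross
the plane overlap/2 short of the equator (or earlier at the barrel radius)
into an axis-parallel segment ending overlap/2 beyond the equator, producing
an antiparallel overlap region of configurable width (default 2 µm).  No
quantitative claims rest on this construction; it exists to probe how the
midzone architecture affects kinesin accumulation.

**Centrosome maturation** schedules hold per-centrosome piecewise-linear
filament counts and trajectories.  Filament direction vectors are
pre-generated per centrosome so identities are stable; the geometry is
regenerated at a coarse interval (default a few seconds of simulated time),
new filaments appear instantly at full length, and a moving centrosome
carries its filaments and their bound particles rigidly (arc coordinates
preserved).  Rigid translation preserves bound counts, which is the
quantity these scenarios track.

### Pole-proximity convention

Minus ends live on a 1 µm nucleation sphere around each pole, so a particle
parked at a minus end is exactly 1 µm from the pole *centre*.  All
pole-distance histograms and proximity fractions therefore measure distance
from the nucleation-sphere *surface* (clamped to zero inside it); the
concentration index (1/mean distance to the nearest organizing centre)
uses centre distances, as its normalization is immaterial for the
comparisons it serves.

## Calibration tier

One filament cross-section (radius 12.5 nm) sits at the centre of a 2D
periodic box of side density^(−1/2).  The particle centre reflects off the
contact circle (R_M + r) and binds when it lands within d₀ of it; unbinding
(rate k_off) releases it at its binding point.  The stationary bound
fraction f — time-averaged after a burn-in of 10/k_off over an ensemble of
independent walkers (default 48 walkers × 400 s) — gives
k_on = k_off·f/(1−f), with a between-walker standard error.  The 2D walk
uses the same D_C as the 3D engine; this is an approximation justified by
the diffusion-limited treatment of the encounter step.

Two internal consistency checks accompany the estimate: the mean bound
interval must reproduce 1/k_off, and the transient bound fraction from an
all-free start must follow the two-state mean-field relaxation
f∞(1 − exp(−(k_on + k_off)t)) with the stationary k_on — the compatibility
bridge between the agent and mean-field tiers.

With the default parameterization the box yields k_on ≈ 4.8 s⁻¹ at
3 filaments/µm² for a 5 nm particle.  The size dependence is weak — the
capture shell's width is set by d₀, so only its circumference grows with r —
measuring ≈1.45× between 1 nm and 10 nm particles at that density and
rising toward ~1.75× only at densities (≥300 µm⁻²) where volume exclusion
becomes significant.

## Mean-field tier

### Domain

A 35 × 35 × 14 µm block with corner-origin coordinates, z measured downward
from the cortex surface.  The top `energid_depth` = 7 µm are subdivided
5 × 5 by impermeable vertical walls spanning from the surface down to
`wall_depth`; below the walls the space is continuous.  The "gap width"
between neighbouring energids is the unwalled depth H − wall_depth (a 7 µm
gap means walls span the top 7 µm).  Binding (k_b = k_on) acts only inside
the sequestration mask, by default the top energid layer.  The grid spacing
must divide all box dimensions and the wall pitch; 0.5 µm is the reference
spacing.

### Discretization

Finite volume on the regular grid.  Diffusion of the free phase (and of the
bound phase when D_M > 0) is advanced by backward Euler through a one-time
sparse LU factorization of I − Δt·L, where L carries zero transmissibility
across walls and outer boundaries — unconditionally stable and
mass-conserving to solver precision.  The local binding/unbinding pair is
integrated exactly per cell (exponential relaxation toward the local
equilibrium partition), and the two half-reaction/diffusion stages are
composed by Strang splitting.  Optional bound-phase advection along an
orientation field uses conservative first-order upwind with a CFL guard; it
is off in the cortex scenarios, where the bound phase is effectively
immobile (V = 0, D_M ≪ D_C) and the exact uniform-ρ_f steady state
(ρ_b = k_b/k_u·ρ_f inside the mask) is available analytically as the
pre-bleach initial condition.

### Protocols

**FRAP**: from the sequestered steady state, both densities inside the
bleach box (default: the central energid, full energid depth, 100% bleach
depth) are scaled down at t = 0; the recovery curve is the total
concentration at the bleached-energid centre normalized by its pre-bleach
value.  The recovery time is operationalized as the first time the curve
reaches 90% of its long-time plateau (tail mean).  On the reference
parameterization (k_on = 5 s⁻¹, k_off = 1 s⁻¹, D = 20 µm²/s) this gives
≈27 s, grid-converged to within ~4% between 1.0 and 0.7 µm spacings; note
that at 40 s the same curve sits at ≈95% of its plateau, so shifting the
(inherently conventional) threshold from 90% to 95% moves the reported
recovery time from ~27 s to ~40 s.  The pure-diffusion control instead
equalizes the bleached and neighbouring energid centres within a few
seconds (the evening-out time is defined as the centre-to-centre difference
falling below 5% of its initial value).

**FLIP**: the bleach box is held at zero concentration continuously (a
perfect sink, duty cycle not modelled); side-view snapshots at requested
times show the superposition of the lateral bleach gradient and the
vertical sequestration gradient characteristic of a cortex that binds its
cargo.

**Phenomenological D**: the pure-diffusion coefficient whose recovery curve
(same domain and protocol, binding off) minimizes the RMS distance to a
given curve, found by bounded scalar minimization in log D to 1% relative
tolerance after a seven-point coarse scan (which warns if the objective is
not unimodal).  For the sequestered reference curve this yields ≈2.7 µm²/s
over a 100 s window — binding slows transport roughly sevenfold, bracketed
by the fast-exchange closed form D·k_u/(k_b + k_u) = 20/6 ≈ 3.3 µm²/s.

## Scenario presets and problem sizes

Full-scale runs use 1000 particles; every preset accepts a `scale` factor
and duration override so reduced ensembles (50–300 particles, 10–120 s,
three replicate seeds) run in seconds to minutes on one CPU.  Equilibrium
metrics are read from the final snapshot or averaged over the last fifth of
the run (plateau window); sweep outputs carry per-seed rows so standard
errors can be formed.  The acceptance script runs the desk-scale sizes and
records them beside each value; the 0.7 µm (recovery times) and 1.0 µm
(D fit) grids are its PDE problem sizes.

The pole-to-pole turnover of a mature spindle is far too slow to observe
directly at desk scale; it is bounded from below by counting pole switches
in a reduced run and inverting the Poisson wait-time model
prob(wait < t) = 1 − exp(−t/τ).  Note the exact inversion
τ = −t/ln(1 − p): for p = 0.003 at t = 3000 s it gives τ ≈ 1.0 × 10⁶ s
(≈ t/p for small p).

## What the synthetic conditions do and do not emulate

The scenarios generate their own inputs: seeded random filament arrays and
particle ensembles at the parameter-table values, not measured cell
geometries.  They capture the density, polarity and connectivity of the
arrays, but not filament dynamic instability or bending (filaments are
static rigid cylinders), particle–particle crowding, motor force–velocity
relations, multi-motor cargoes, or photophysics (reversible bleaching,
blinking) — so agreement in these tests demonstrates the claimed
network-level sequestration mechanics, not a calibrated reconstruction of
any particular embryo.

## Numerical choices and degenerate inputs

* Δt defaults to 10⁻⁴ s and is part of the binding parameterization (see
  above); k·Δt ≫ 0.1 also warns.
* Geometry validation rejects coincident poles, out-of-cell nucleation
  centres and trajectories, non-positive filament lengths, and grid
  spacings that misalign with walls; empty filament sets and zero-count
  spindles are valid and produce pure-diffusion behaviour.
* The proximity-grid cell size (0.25 µm) exceeds the binding threshold by
  an order of magnitude, the condition under which the 27-cell query is
  exact for binding decisions.
* Negative PDE densities beyond tolerance abort the solve (they indicate a
  scheme bug, not a parameter problem); the reaction update is exact and
  positivity-preserving, and backward-Euler diffusion is an M-matrix solve.
* Turnover-time inversion rejects p ∈ {0, 1}; the asymmetric index rejects
  empty partitions.

## Known limitations

* The calibration's particle-size dependence (≈1.45× per decade of radius
  at reference density) is set by the d₀-wide capture shell; treatments
  that let the capture width itself grow with r would steepen it.
* Mean-field bound-phase advection is first-order upwind and lightly
  exercised; the cortex scenarios do not use it.
* The maturation engine regenerates geometry at a coarse interval, so a
  moving centrosome's filaments translate in hops of that interval.
* At 0.5 µm spacing a full FRAP solve costs tens of minutes on one CPU
  (the sparse factorization dominates); the shipped protocols use 0.7–1.0
  µm, where the recovery curve differs by <2% RMS from the halved-spacing
  solution.
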