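# mtseq

Simulation toolkit for **microtubule-mediated spatial regulation** of
intracellular components: how a dense, polarized filament network — a mitotic
spindle, a centrosomal aster, or the cortical cytoskeleton of a syncytial
*Drosophila* embryo — sequesters molecules that bind it, concentrates
motor-driven cargo at spindle poles, partitions fate determinants between
unequal centrosomes, and slows effective diffusion enough to explain delayed
FRAP/FLIP exchange between neighbouring energids.

The package is aimed at cell biophysicists who want to reproduce or extend
these model results: it provides the geometry builders, the stochastic
engine, a mean-field solver and ready-made scenario presets behind both a
Python API and a small `mtseq` command-line tool.

## The model

**Agent-based tier.** Each particle is a sphere of radius *r* = 5 nm.  Free
particles diffuse in a spherical cell of radius *R_C* = 10 µm,

&nbsp;&nbsp;&nbsp;&nbsp;x(t+Δt) = x(t) + √(2 D_C Δt)·η,&nbsp;&nbsp;η ~ N(0,1) per axis,

with specular reflection at the cortex.  A particle binds a microtubule
(static cylinder, radius *R_M* = 12.5 nm) when the surface gap falls below a
critical distance *d₀* = 0.8 nm, i.e. when its centre comes within
*R_M + r + d₀* = 18.3 nm of the filament axis.  Bound particles unbind with
first-order rate *k* = 1 s⁻¹ and meanwhile translocate along the filament at
the motor speed *V* = 1 µm/s — toward minus ends (the organizing pole) for
dynein, toward plus ends for kinesin — plus on-filament diffusion
*D_M* = 0.01 µm²/s.  Spindle poles are reflecting (arc-length reflection at
the minus end); walking off a plus end detaches the motor.  Defaults:
Δt = 10⁻⁴ s, D_C = 2 µm²/s, 800 spindle + 800 astral microtubules per pole
nucleated on a 1 µm sphere around each pole, spindle filaments inside the
45°-half-angle cone toward the mid-plane.

**Calibration tier.**  A 2D periodic box with one filament cross-section
(side = density^(−1/2)) maps microtubule areal density to an effective
mean-field binding rate via the stationary bound fraction *f*:
*k_on = k_off · f/(1−f)*.

**Mean-field tier.**  Free/bound concentrations ρ_f, ρ_b on a rectangular
cortex block (35 × 35 × 14 µm) obey

&nbsp;&nbsp;&nbsp;&nbsp;∂ρ_f/∂t = D_C ∇²ρ_f − k_b ρ_f + k_u ρ_b,
&nbsp;&nbsp;&nbsp;&nbsp;∂ρ_b/∂t = (bound transport) + k_b ρ_f − k_u ρ_b,

with no-flux outer boundaries, impermeable furrow walls subdividing the top
7 µm into 5 × 5 energids, and binding (k_b = k_on) active only in that top
layer.  FRAP and FLIP protocols run on this solver.

## Worked example

```python
from mtseq.scenarios import fig1_symmetric
_, report = fig1_symmetric(scale=0.2, duration=20.0, seeds=(1, 2, 3))
print(report["frac_within_200nm"], report["frac_within_1um"])
```

```
0.9983333333333334 1.0
```

With 200 dyneins per seed started uniformly in the cell, after 20 s
essentially all particles (99.8% pooled over three seeds) sit within 200 nm
of a spindle-pole surface, and every particle is within 1 µm — the spindle
acts as a near-perfect trap for minus-end-directed cargo.  The same run
reports the bound fraction (`report["bound_fraction"]`, here 0.995).

From the shell, the 2D calibration at a density of 3 filaments/µm²:

```bash
mtseq calibrate --density-grid 3 --radii 0.005 --duration 120 --out curve.csv
```

```
 density  radius  bound_fraction       se     k_on  k_on_se
     3.0   0.005        0.823159 0.003434 4.654813 0.109807
```

i.e. an effective binding rate of ≈4.7 s⁻¹ — the value used for the
Dorsal-protein FRAP/FLIP scenario (k_on = 5 s⁻¹, k_off = 1 s⁻¹).

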