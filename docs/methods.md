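# Methods

## Scope and model

The package models oxygen transport in avascular tissue spheroids whose
shape is given implicitly by a continuous defining function *f* (positive
inside, zero on the surface). The oxygen partial pressure P(r, t) in mmHg
obeys a diffusion equation with a constant volumetric sink,

    ∂P/∂t = D ΔP − OCR,

with a Dirichlet condition P = P_b on the surface. The assumptions are the
standard ones for mature spheroids in culture: oxygen concentration is
proportional to partial pressure; consumption is zero-order (independent of
local pO₂) wherever oxygen is present; the geometry does not change during
a simulation (diffusion is far faster than growth or fusion); the
surrounding medium is well mixed, so the surface pressure is constant.

Default physical parameters (all configurable):

| parameter | default | units | meaning |
|---|---|---|---|
| D | 2×10⁻⁹ | m²/s | oxygen diffusivity in cellular tissue |
| OCR | 20 | mmHg/s | volumetric oxygen consumption rate |
| P_b, P_init | 140 | mmHg | DMEM culture-medium oxygen partial pressure |
| dt | 0.05 | s | backward-Euler step |
| output_every | 0.25 | s | sampling interval of the minimum-pressure series |

For a smooth sphere the steady state is P(r) = P_b − OCR·(R² − r²)/(6D);
with the defaults the center of a 300 μm spheroid sits at 102.5 mmHg and
the center reaches 100 mmHg at d ≈ 309.8 μm and 50 mmHg at d ≈ 464.8 μm.
These closed forms are the primary oracles of the test suite.

## Geometry

Spheres use the signed Euclidean distance f = R − ‖x − c‖ rather than the
algebraic form R² − ‖x − c‖², so field values carry length units and the
blend displacement a₀ and noise amplitudes have direct geometric meaning.

Surface irregularities are Gardner solid noise, a deterministic product of
three nested-sinusoid factors (per-factor amplitude *a*, frequency *q* in
rad/μm, dimensionless phase *p*; the factor constants 1.17 and 1.35 follow
the classical formulation). Each factor is bounded by a·(1 + 1/1.17), so
|GN| ≤ (1.8547·a)³; that bound pads bounding boxes and calibrates the
default study amplitude (see below). Noise is added to the defining
function in coordinates relative to the spheroid center, so a spheroid's
surface texture is intrinsic to it; in a fused pair each spheroid carries
its own local noise field.

Fusion composes two spheroid fields with the Rvachev union
R_un = f₁ + f₂ + √(f₁² + f₂²) (sign-equivalent to max) plus the
Gaussian-type displacement d = a₀/(1 + (f₁/a₁)² + (f₂/a₂)²), which peaks
exactly where both surfaces meet and adds the neck material seen in fusing
spheroids. Defaults, scaling with the constituent radius R: center
separation 1.5 R (a moderate fusion stage), a₀ = 0.2 R, a₁ = a₂ = R.
These are package choices — the blend and separation values are genuinely
open parameters — and every one is exposed in the configuration.

## Surface extraction

Planar slices use marching squares (scikit-image) on a uniform 2D sampling
of *f*, with loops labelled by the connected interior component they bound.
Full surfaces use marching cubes with an unambiguous case table
(scikit-image's Lewiner implementation) rather than stitching slice stacks:
this guarantees closed, consistently oriented output. In both cases the
linear-interpolation crossing vertices are refined by bisection of *f*
along their grid edge to `root_tol` (default h/100); bisection is used
because defining functions carry no derivative information. Grid nodes that
land exactly on the surface are nudged infinitesimally inside before
contouring — exact zeros at nodes are degenerate for the case tables and
can open pinholes in the mesh.

STL files (ascii or binary) carry no units; the package convention is that
STL coordinates are micrometres, recorded in the file header comment.
Reading an STL welds bitwise-identical corners; distinct surface points
closer than the float32 file resolution collapse in that welding, and the
zero-area triangles left behind are dropped so the edge-manifold
(watertightness) property survives a round trip. Reading with
`merge_vertices=False` preserves the triangle soup exactly.

## Finite-volume solver

The solver is an embedded-boundary scheme on a uniform Cartesian grid:
cells whose center has f > 0 are cubic control volumes; faces between two
interior cells carry the flux D·(P_j − P_i)/h per unit area; faces against
exterior cells are Dirichlet boundary faces. Cell membership is decided by
the center-sign test alone (no cut-cell volume fractions) — the geometric
error this introduces is part of the observed convergence behaviour.

Where the Dirichlet value is imposed matters. The textbook choice puts it
at the face, a fixed h/2 from the cell center (`boundary_offset="half"`);
measured against the analytic sphere solution its L∞ error converges at
only ≈ 0.8 order, dominated by the staircase misplacement of the boundary.
The default (`boundary_offset="interface"`) therefore finds the actual
f = 0 crossing along each boundary-face axis by bisection and imposes the
value at that distance (clipped to [0.01 h, h] to bound the matrix
conditioning). With the sharp interface the convergence study measures an
observed order ≈ 2 and the R = 150 μm steady minimum lands within ~0.02 %
of the closed form. Both variants are kept; the h/2 form also admits the
exact single-cell balance P_b − OCR·h²/(12D) used as a unit test.

Time integration is backward Euler with the diffusion operator implicit and
the constant sink explicit; the systems (I/dt + D·A) P⁺ = … and the steady
D·A P = … are symmetric positive definite, ordered lexicographically, and
solved by conjugate gradients to relative residual ≤ 10⁻¹⁰ (CG converges in
well under a second up to ~5×10⁵ unknowns here; a direct sparse-LU fallback
guards the rare non-converged case). Everything is deterministic.

Negative pressures are unphysical but a constant sink can produce them in
large spheroids. Clamping (default on) enforces the complementarity
solution: transient steps clamp at zero; the steady solve uses an
active-set iteration in which cells with negative unconstrained pressure
are fixed at P = 0 with consumption switched off, and fixed cells whose
diffusive supply would exceed OCR are released, iterated to a fixed point.
A d = 900 μm spheroid then shows the expected anoxic plateau at exactly
0 mmHg.

Units: geometry and grids are in μm, physics in SI internally, pressures in
mmHg throughout.

## Analyses and study conditions

**Diameter sweep.** Steady solves over a list of diameters (geometry fixed
during each solve), then a decreasing isotonic regression — weighted
least-squares under a monotonicity constraint, solved by
pool-adjacent-violators with fitted values clipped to the physical range
[0, 160] mmHg — interpolated piecewise-linearly between knots to locate
threshold crossings. 100 mmHg marks the end of the safe range, 50 mmHg the
onset of necrosis; the smallest crossing diameter is returned on flat
segments. Default sweep: 200–400 μm in 20 μm steps at 20 cells per radius,
which reproduces the safe boundary at 309.6 μm (closed form 309.8 μm) in a
few seconds.

**Early dynamics.** Each transient is summarised by an ordinary
least-squares line P̂(t) = A + B·t through the first 10 samples of the
spatial-minimum pressure (raw by default; a log transform is available).
While the diffusive influence of the boundary has not yet reached the
deepest interior point, B ≈ −OCR. That window closes at roughly the center
diffusion time R²/(π²D): for d = 400 μm this is ≈ 2.0 s, *inside* the
default 10-point window (0–2.25 s), so the fitted B for such spheroids is
≈ −18 mmHg/s rather than −OCR — confirmed independently by a fine 1D
spherically symmetric finite-difference solution in the test suite. Over
[0, 0.5] s the slope does match −OCR within 2 %.

**Noise influence study.** One noisy spheroid per design point, all rows on
a single fixed voxel grid sized for the largest amplitude in the design.
Default design: full factorial a ∈ {0, a_ref, 2 a_ref}, q ∈ 2π/R·{1, 2, 4},
p ∈ {0, 0.5, 1}, with a_ref set so the worst-case surface displacement
(1.8547·a_ref)³ equals 10 % of R; a seeded uniform random design is the
alternative. The default study radius is 150 μm — the scale of the
"optimal" spheroids identified by the sweep — at 10 cells per radius with a
2.5 s transient. Responses A and B are tested against (a, q, p) by OLS
with per-coefficient t-tests at the Bonferroni-adjusted threshold
0.05/2 = 0.025, and by Automatic Relevance Determination
(sklearn's ARDRegression on raw features, matching how such models are
usually reported), whose per-coefficient Gaussian priors prune irrelevant
predictors.

Under these conditions phase has no effect (ARD coefficient < 0.1 % of the
response spread; OLS p ≈ 0.6–1.0) and frequency is not significant by OLS
(p ≈ 0.06–0.22). Amplitude, however, is a real effect at the 2 a_ref level
of this design: the worst-case displacement there is 0.8 R, which
substantially reshapes the solid, and its interaction with frequency
(large low-frequency lobes move the deepest interior point much more than
high-frequency ripples) leaves a nonzero ARD frequency coefficient in a
main-effects-only model. Grid refinement shrinks but does not eliminate
it. A milder amplitude design, or an interaction-aware model, would be the
natural follow-up for anyone studying that regime.

## What the generator emulates — and does not

The synthetic geometries emulate mature spheroids: smooth spheres,
cell-scale surface roughness (Gardner noise), and fusing pairs with a
smooth neck. They do not emulate growth, cell division, mechanical
deformation during printing, nutrient co-limitation, oxygen-dependent
(Michaelis–Menten) consumption kinetics, or vascularization. Passing tests
therefore show that the transport solver and statistics behave correctly
on biologically plausible *shapes* with the stated constant-rate
consumption physics — not that real spheroids of a given cell line have
these exact thresholds, which shift with D, OCR and the survival-threshold
choice.

## Numerical choices and degenerate inputs

* Linear solves: CG, rtol 10⁻¹², residual verified against 10⁻¹⁰; LU
  fallback. Deterministic cell ordering.
* Bisection tolerances: h/100 for mesh vertices; 40 iterations (≈ 10⁻¹² h)
  for boundary-face distances.
* Boundary-face distance clip: [0.01 h, h].
* Exact-zero field samples are nudged inside before contouring.
* Empty geometry (no interior cell, or an all-negative field) raises a
  dedicated error; interiors touching the grid border are rejected —
  callers must leave at least one exterior cell of padding.
* Isotonic ties: on flat fitted segments the smallest crossing diameter is
  returned; thresholds outside the fitted range raise.
* Active-set iteration is capped (default 100) and raises with diagnostics
  if it cycles.

## Problem sizes

Default test and analysis sizes were chosen so the whole suite runs on one
CPU in well under a minute of solver time: sweeps use 20 cells per radius
(~3×10⁴ interior cells at d = 400 μm), the convergence study refines 8 →
16 → 32 cells per radius (~1.4×10⁵ cells at the finest level), and the
noise study uses 27 design points at 10 cells per radius. All scale up by
configuration if more accuracy is wanted.

## Known limitations

* Constant-rate consumption overstates oxygen demand near anoxia; the
  complementarity clamp is a coarse stand-in for saturable kinetics.
* The cell-center membership rule makes the discrete volume differ from
  the true volume by O(h); thin necks or noise spikes below the grid scale
  are dropped silently.
* The 10-point linear summary conflates two regimes for spheroids whose
  center diffusion time is shorter than the window (see above).
* The noise study's statistical layer fits main effects only.
* Fused-pair results depend on the separation and blend defaults; no
  attempt is made to model the time course of fusion itself.
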