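# Methods

This note records the model, the numerical choices, and the reasoning
behind the defaults, in the order the pipeline runs.

## Geometry

The physical perfusion chamber is represented by a canonical
axisymmetric reconstruction: inlet tube → bottom plenum → scaffold disc →
top plenum → outlet tube, coaxial. Only the scaffold dimensions (8 mm
diameter × 3 mm height) are measured quantities; the remaining lengths
are reconstructions chosen once:

| parameter | default | rationale |
|---|---|---|
| scaffold radius/height | 4.0 / 3.0 mm | disc as punched |
| chamber radius | 4.0 mm | press-fit scaffold; consistent with peak shear appearing against the chamber wall |
| tube radius | 1.025 mm | the two pump operating points (0.2 and 12 ml/min) and the two nominal mean inlet velocities (0.001 and 0.061 m/s) are mutually consistent through v = Q/(πr²) only for d ≈ 2.05 mm |
| tube length | 10 mm | ≫ laminar entrance length at the low operating point |
| plenum heights | 5 mm | order of the chamber radius |

All lengths are overridable from the TOML config. Cells are labeled by a
cell-center point-in-region test with half-open conventions (a center
exactly on the free/porous interface is porous; a center exactly on the
solid envelope is solid).

**Grid spacings.** The default spacing ladder (205 → 102.5 → 51.25 μm)
is commensurate with the tube radius, so the tube wall falls exactly on
a grid face. With incommensurate spacings the rasterized tube radius is
quantized to the nearest face and the developed tube peak (2× the mean
velocity) inherits a non-vanishing O(Δr) bias (≈ 5% at 50–100 μm); on
the commensurate ladder the mirror-ghost no-slip is second-order and the
peak is recovered to ≈ 1%.

## Flow solver

Single-field Brinkman penalization: one steady incompressible momentum
equation everywhere with the drag −(μ/k)u switched on in porous cells.
This avoids free/porous interface conditions (continuity of velocity and
stress is implicit in the single field) and matches the behavior of
coupled free-and-porous-media formulations at the averaged-field level.
The effective viscosity in the porous region is μ (not μ/ε): the choice
only matters within a boundary layer of thickness √k ≈ 4 μm, far below
any practical grid.

Discretization: staggered (MAC) axisymmetric finite volumes on a uniform
(r, z) grid. Momentum and continuity are assembled into one sparse
saddle-point system and solved by sparse LU (SuperLU). A direct coupled
solve was preferred over SIMPLE/projection iteration because (a) the
drag coefficient μ/k ≈ 4·10⁷ Pa·s/m² makes segregated schemes stiff
unless the drag is treated implicitly anyway, and (b) discrete
continuity then holds to solver precision in every fluid cell, so mass
conservation is structural rather than iterated-for (observed
inlet/outlet imbalance ~10⁻¹², against a 0.1% requirement).

Boundary conditions: developed parabolic inlet profile with the nominal
mean velocity, discretely renormalized so the revolved inlet flux equals
exactly Q = v·πr² (a plug option exists); zero reference pressure at the
outlet face; no-slip on all walls (normal face velocities vanish;
tangential no-slip via mirror ghosts). The parabolic inlet reflects the
long upstream tubing of a real pump circuit, and it decouples the
carried flow rate from how the tube cross-section rasterizes.

Convective inertia is included by default (Picard relinearization,
first-order upwind, relaxation 0.85). The tube Reynolds number is ≈ 3 at
the low and ≈ 180 at the high operating point; Picard converges in ~15
iterations at the high point. A Stokes-only flag keeps the operator
linear for linearity tests (velocities and stresses then scale exactly
with the inlet velocity; the 61× inlet ratio of the two operating points
produces a 61.000… field ratio). Inertia at the low point changes the
scaffold peak velocity by < 2%, consistent with Re ≪ 1 inside the
scaffold.

Mesh convergence follows the 2% rule: spacings are halved until the
volume-weighted mean velocity magnitude (revolved cell volumes) changes
by less than 2% in both the free and the porous domain between
consecutive levels. "Mean velocity" is not otherwise defined for this
rule; the volume-weighted magnitude is the natural reading. On the
canonical geometry the sweep terminates at 51.25 μm (~8·10⁴ unknowns,
seconds per Stokes solve, ~20 s with inertia at the high operating
point).

## Shear stress

τ = μ√(2 D:D) at cell centers, with the axisymmetric strain-rate
components D_rr = ∂u_r/∂r, D_θθ = u_r/r, D_zz = ∂u_z/∂z,
D_rz = ½(∂u_r/∂z + ∂u_z/∂r); the off-diagonal derivative lives at grid
corners and is averaged back to centers. This is the standard
"shear rate × viscosity" CFD output. Two caveats are deliberate:

- Absolute τ maxima are grid-sensitive. The Brinkman wall layer (√k ≈
  4 μm) is unresolvable, so the peak against the chamber wall grows as
  the grid refines (0.26 → 0.51 mPa between 102.5 and 51.25 μm at the
  low operating point). Peak values are model outputs to be compared at
  a stated resolution, not ground truth.
- The averaged-field τ underestimates pore-level stresses; no pore-scale
  correction is attempted.

Revolution onto a voxel lattice interpolates τ bilinearly in (r, z)
(clamped to the nearest cell within half a cell of the grid edge);
voxels whose centers fall outside the fluid domain are flagged invalid
and carried as NaN, never silently zero.

## Micro-CT processing

"Filter width 1.2, support 1" is interpreted in the scanner-vendor
convention: Gaussian σ = 1.2 voxels truncated at a 1-voxel radius (3³
taps) and renormalized to unit sum, mirror boundaries. Segmentation
threshold 97.5 mg HA/cm³ with the ≥ convention (a voxel exactly at
threshold is mineralized; the convention is not dictated by the
calibration and had to be fixed one way). Particle filtering removes
components *strictly* smaller than 50 voxels ("smaller than" read
strictly, so 50-voxel components survive); foreground connectivity is
26-neighborhood by default with 6-neighborhood available. TV is the
nominal scaffold cylinder mapped into image coordinates — the scaffold
itself is invisible at this threshold, and the envelope is the only
lattice-independent total volume. Time-lapse series are assumed
pre-registered on a common lattice; no registration is implemented.

## ROC

The sweep uses the exact unique τ values as thresholds (descending, with
a +inf sentinel so the curve starts at (0,0); the smallest threshold
includes every voxel, ending at (1,1)); tied voxels change
classification together. Prediction direction is fixed to "high stress ⇒
mineralized". AUC is the trapezoidal integral, which on this sweep
equals the Mann–Whitney statistic exactly (tested against a double-loop
oracle and scikit-learn). The least-random point maximizes TPR − FPR
(equivalent to the furthest-from-diagonal point since the perpendicular
distance is (TPR−FPR)/√2), ties broken toward the larger threshold. The
analysis region is the scaffold envelope *including* scaffold-material
voxels — scaffold material cannot be separated from medium in the scans,
which inflates the negative count; an erosion option exists but is off
by default. All scaffolds are pooled into one analysis.

## Synthetic data: what it emulates, and what it does not

The generator exists so every stage is testable without scan data; its
defaults are the study conditions:

- **Phantom**: spherical pores with diameters uniform in 315–400 μm
  (the salt sieve fraction), overlap allowed (packed granules touch),
  carved until the measured pore fraction is within ±2% of the 55%
  target. 55% is the porosity of the porous-flow model; the real
  material is far more porous (~90%) at scales the averaged model does
  not represent, which is why porosity is a parameter and not a claim.
- **Mineralization**: per-week hazard rate·link(τ) + bonus·(mineralized
  neighbor fraction), clipped to [0,1]; masks are nested (no
  demineralization). Defaults rate = 0.6/week and bonus = 0.35 were
  chosen once so that five weekly rounds grow a contiguous shell thick
  enough to survive the acquisition blur and produce final BV/TV of
  order 1–2%, the magnitude seen in mineralizing cultures. Edge-to-center
  growth under flow is emergent: the 0.55–24 mPa band sits peripherally
  in perfused fields, and the neighborhood bonus sharpens the front. The
  uniform link (static condition) mineralizes uniformly. No claim of
  biological kinetics calibration is made; the hazard model's purpose is
  exercising the pipeline.
- **Acquisition**: assigned mineral density 200 mg HA/cm³ (comfortably
  above the 97.5 threshold), scaffold material 30 mg HA/cm³ (invisible,
  as in reality), Gaussian PSF σ = 0.5 voxels, noise SD 15 mg HA/cm³.

Consequently, passing tests show the *pipeline* is correct and the
stress→mineralization link is *recoverable* under the stated acquisition
model; they say nothing about real tissue kinetics, scanner physics
beyond blur+noise, or registration errors (absent by construction).

## Numerical/edge-case conventions

- Zero inlet velocity ⇒ identically zero field, constant pressure, mass
  imbalance defined as 0.
- Picard divergence (update growing over 6 consecutive iterations) and
  tolerance failure raise errors carrying diagnostics; the refinement
  sweep raises with the full report attached if the 2% rule is not met
  within the level budget (criterion 0 therefore always errors).
- ROC is undefined (error) when either class is empty.
- NIfTI headers store spacing/origin in float32; MetaImage round-trips
  them at full precision and is the default artifact format.
- Every stochastic stage consumes an explicit seed recorded in the run
  manifest; identical config + seed reproduces bit-identical artifacts.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: refinement
ladder 205 → 51.25 μm (~8·10⁴ unknowns at the converged level);
validation tubes at 51.25–100 μm; synthetic volumes at 125 μm voxels
(64×64×24 lattice, ~7.7·10⁴ analysis voxels). These sizes resolve every
quantity the package reports at the few-percent level while keeping a
full acceptance run around a minute; the 36 μm production voxel size and
finer grids are configuration changes, not code changes.

## Known limitations

- No pore-scale CFD, turbulence, transients, fluid–structure
  interaction, or permeability feedback from growing tissue.
- The bioreactor-volume velocity maximum at the high operating point
  depends on inlet-tube entrance flow and the unavailable physical CAD;
  it is reported but not a reproduction anchor.
- Whether the original model included inertia and which Brinkman
  viscosity closure it used is unknown; both are exposed as options
  (defaults: inertia on, closure μ).
- BV/TV uses the scaffold envelope as TV; using the full scan field of
  view instead would rescale all BV/TV values by a constant factor.
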