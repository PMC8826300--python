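# Methods

This note documents the models, numerical choices and limitations of
`avfsi`, in the spirit of a solver manual: what is computed, which knobs
matter, and what the desk-scale results do and do not demonstrate.

## Scope and reduction

The package simulates systolic ejection through the aortic valve as a 2D
long-axis mid-plane problem: an idealized left ventricle (LV), outflow
tract, sinus bulge and ascending aorta (AAo), with two leaflets.  The 2D
reduction is chosen because the in-plane Fung strain-energy exponent is
already written in the components (E11, E22, E12), and all coupling,
refinement and metric machinery is dimension-independent.  Walls are rigid
(aortic compliance excluded), the mitral valve is fully closed during
ejection, and only systole is simulated (no diastolic closure under
back-pressure).  Patient-specific 3D magnitudes are explicitly not a
target; the configuration comparisons are ordinal.

## Fluid

Incompressible Navier–Stokes in dimensional form with Newtonian blood,
ρ = 1060 kg/m³ and μ = 3.5 mPa·s by default (these reproduce the
Re ≈ 10⁴ regime from a ~1 m/s mean velocity in a 3.3 cm aorta).  MAC
staggered grid; Adams–Bashforth-2 convection (second-order upwind by
default, central optional); Crank–Nicolson diffusion (the viscous time-step
limit would otherwise dominate at verification viscosities); pressure
projection with a sparse-direct (LU) Poisson solve restricted to fluid
cells, one pressure anchor per connected fluid component, and the pressure
gauge fixed at the outlet mean.  Verified: Poiseuille centreline/mean
= 1.5 within 1%, Taylor–Green energy decay within 2% of the closed form,
spatial convergence order ≥ 1.8 (measured ≈ 2–3), machine-precision
discrete divergence.

Immersed boundaries: cells with any level set ≤ 0 are solid; faces touching
solid are forced to the local interface velocity, with ghost-fluid mirror
extrapolation (`u_ghost = 2 u_Γ − u_mirror`) within 1.5 cells of the zero
contour so the forcing varies continuously with sub-cell interface motion.
The no-slip error at immersed contours converges at first order or better
(spinning-disk test).  Fresh cells are filled from wet neighbours.  Global
mass is closed exactly every step: the prescribed outlet flux equals the
shoelace-rate of volume displaced by all moving interfaces, and each fluid
component's residual boundary-flux mismatch (a staircase discretization
error) is distributed over its forced faces, never over the outlet.

## Structure

Total-Lagrangian 4-node quadrilaterals with a 4-mode enhanced-assumed-strain
field (centre-Jacobian mapped, det-scaled, so the constant-stress patch test
passes identically).  Strain vector (E11, E22, γ=2E12) with S12 = ∂W/∂γ —
an engineering-shear convention used consistently in the material law,
kinematics and geometric stiffness; the isotropic-matching helper
(`isotropic_fung_constants`) makes the exponent a true isotropic invariant,
which the objectivity test exercises.  Verified: stress and tangent match
finite differences of W to 1e-6 over 1000 random states; slender cantilever
(length/thickness 100, 20×1 elements) within 5% of Euler–Bernoulli with EAS
while plain bilinear quads underpredict by more than 30%.

Newmark time integration: β=1/4, γ=1/2 (non-dissipative; < 1% energy drift
over 1000 free-vibration steps) for structural analysis; the coupled valve
runs use γ up to 1 (β=(γ+½)²/4) to damp spurious interface ringing at
desk-scale resolution — a deliberate, config-exposed trade of high-frequency
fidelity for robustness.  The Newton loop uses a backtracking line search,
load continuation and Levenberg regularization near buckling states, and
falls back to a best-effort iterate deep below the load scale when a
transient sub-iterate load is extreme (the outer relaxation absorbs it).

Shipped leaflet materials: the exponent constants are literature-scale for
aortic leaflet tissue; the stress scale c and the strip thickness are set so
the 2D strip's *bending rigidity* stands in for the combined
bending/membrane/commissural support of a 3D leaflet (a 2D strip at raw
tissue moduli has no membrane support and flutters freely).  Stenosis:
c × 10 uniformly, guarded against double application.  The prosthetic set is
stiffer pericardium on a 23 mm-class ring.

## Coupling

Strong partitioned (Dirichlet–Neumann) coupling: per time step the loop
{fluid solve → side-aware traction sampling → leaflet Newmark solve →
Aitken-relaxed interface update} iterates to a displacement-increment
tolerance.  Key choices, all config-exposed:

* **Aitken relaxation**: classic vector secant, magnitude-clamped but
  sign-free (a negative secant estimate is what handles monotone-divergent
  modes), warm-started across steps.  The thin leaflet in blood has an
  added-mass amplification ρ_f L/(ρ_s t) of order 20–40, so stable
  relaxation factors are far below flap-benchmark folklore.
* **Artificial added mass**: the structural sub-solve carries an interface
  mass term m_a(a − a_iterate) with m_a ≈ ρ_f·L per unit surface.  It
  cancels identically at sub-iteration convergence (the converged step is
  unchanged) but divides the added-mass gain of the iteration map, which is
  what lets Aitken operate with useful ω.  Disabling it reproduces the
  textbook divergence.
* **Frozen per-step geometry**: level sets, masks and sampling stencils are
  built from the predicted configuration and frozen across the step's
  sub-iterations; only velocities, tractions and the structural state
  iterate.  This keeps the fixed-point map continuous (no cell toggling
  between iterates) and factorizes the implicit operators once per step.
  The geometric lag is O(dt·|v|), the order of the splitting.
* **Side-aware load sampling**: leaflet surface tractions are sampled per
  side from same-side fluid cells only (nearest same-side fill).  In thin
  root/tip wedges, side-blind sampling reads the opposing face's pressure
  and makes the added-mass feedback repulsive.
* **Tolerance**: the benchmark default is 1.0e-6 (relative ∞-norm of the
  interface increment scaled by the aortic diameter), demonstrated on the
  flexible-flap benchmark.  The valve runs use an adaptive threshold
  clipped to [2e-5, stall level], proportional to the per-step interface
  motion: slow phases must converge much tighter than fast ones or residual
  jolts accumulate into structural ringing.  Near-contact film states are
  genuinely non-contractive for scalar relaxation (the valve snapping open
  is a λ>1 quasi-static mode); a bounded stall acceptance (best iterate,
  logged) regularizes those steps at desk scale.
* **Gap floor and contact**: a smooth blended lift keeps a fluid film of
  ~3 cells between leaflets (the flow problem never seals); soft penalty
  forces keep leaflet centerlines off the walls, the static obstacles and
  each other (2D leaflets lack 3D commissural support).  Tractions,
  interface velocities and solved fluid velocities carry generous physical
  ceilings that only clip solver transients.

The flexible-flap benchmark (flap clamped transverse to a piston-driven
channel at density ratio 1.0) converges every step within the 50-iteration
cap under dynamic Aitken and exceeds the cap within a few steps at fixed
ω = 1 — the added-mass rationale made testable.

## LV driver

The spatial contraction rate is the printed product-of-Gaussians with
b=(−1.4,−1.6,−2.6), c=(0.58,0.5,0.8); the wall arc is mapped into that
frame with the transverse coordinate scaled by the LV semi-axis and the
longitudinal fraction spanning base→apex (the absolute frame of the
constants is not fully determined by the formula; this mapping is the
package's documented choice, and calibration plus the formula itself carry
the physics).  A half-sine temporal envelope peaks mid-systole.  Septal
markers move along the inward normal only; lateral markers add a
longitudinal toward-base component.  The amplitude is calibrated by
bisection (0.1% tolerance) to a prescribed 2D stroke area; the default
stroke of 4 cm² per unit depth keeps desk-grid valve jets in the 0.1–1 m/s
range (a 3D stroke volume has no direct 2D equivalent — the comparative
findings are ordinal and do not depend on the absolute scale).

## Refinement module

The quadtree implements the printed criteria exactly: refine when
|ω|h > ε_ω or |∇u|h > ε_∇u; coarsen when the indicators fall below 0.25 ε.
The printed coarsening joins the indicators with "or", which would coarsen
cells with high velocity gradient but low vorticity; the default is the
conservative "and" reading with `coarsen_logic="or"` available.  2:1
balance is restored by forced refinement after every edit (property-tested
over randomized sequences); transfers are mean-preserving.  The
Navier–Stokes fields of the valve runs live on the uniform base grid; the
quadtree produces per-snapshot refinement maps and the serial load report
(leaf counts per block, imbalance ratio) that a dynamic repartitioner would
consume.  With infinite tolerances the pipeline reduces to the uniform
grid.

## Metrics

All metrics are pure post-processing.  Orifice gap = the contiguous open
run of the valve plane containing the root centreline (sinus recesses
behind the leaflets are not orifice), minimized over a fan of planes;
pseudo-AVA = π(gap/2)², a 2D-derived surrogate reported for qualitative
comparison with clinical valve areas.  Transvalvular gradient =
area-averaged p(LVOT box) − p(AAo box) / 133.322 Pa·mmHg⁻¹, probes one
root-diameter upstream and as far downstream as the truncated domain
allows.  WSS = μ ∂u_t/∂n by second-order one-sided differences at wall
markers.  Q-criterion and Φ = 2μS:S from centred velocity gradients.  Peak
velocity and dissipation are evaluated over the ascending aorta (above the
sino-tubular junction), where the comparative evaluation reads them.
Summary peaks are median-of-3 filtered to reject single-step solver
transients.  Re_AAo uses the systole-mean cross-section speed and the
aortic diameter.

## The comparative experiment at desk scale — what it shows

`workbench.comparative_config()` runs SAV, NAV and TAVR from one anatomy
and driver (identical wall contour and outlet; only leaflets/obstacles
differ) on a ~40×74 grid over an early-systole window (0.03 s), which is
the window in which all three configurations integrate cleanly at this
resolution.  Within it, the structural finding reproduces: the calcified
valve's maximum orifice is smaller than the de-calcified valve's.  The
flow-derived orderings (jet velocity, gradient, dissipation, WSS) do *not*
reproduce at this scale: all leaflets deflect sub-millimetre in the stable
window, so the orifice difference that drives stenotic haemodynamics never
develops, and the flow metrics are instead dominated by leaflet-motion
transients (the stiffer valve is calmer and therefore shows *lower*
unsteady pressure).  Developing the orifice difference requires larger
strokes and longer windows, which at this resolution drive the partitioned
scalar-relaxation coupling into the pop-open/flutter regime it cannot
traverse; the clinical-scale result relies on the 3D sub-cell ghost-fluid
solver at tens of millions of cells.  The full-systole, finer-grid
experiment remains a config change (`grid.base_ny`, `time.duration`), with
cost growing accordingly.

Because the generator is synthetic and 2D, passing tests demonstrate the
correctness and composability of the algorithmic components — not clinical
predictive validity: no patient anatomy, no 3D coaptation mechanics, no
turbulence-resolving resolution, rigid walls, systole only.

## Determinism and I/O

A single seed governs the only optional randomness (wall-contour
perturbation); identical configs reproduce metrics bitwise, and HDF5
checkpoints restart exactly (verified over 10 steps).  Geometry is
serialized as self-describing JSON (cm units); fields as legacy-ASCII VTK;
time series as CSV; configs as TOML round-tripping losslessly.
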