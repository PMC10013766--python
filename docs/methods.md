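# Methods

## Physical model

The package models steady urine drainage through a stented human ureter.
After stent placement, ureteral peristalsis is reduced or abolished, so the
ureter is treated as a rigid straight tube (length L = 270.6 mm, diameter
D = 4 mm) with conical chambers at both ends standing in for the
ureteropelvic and ureterovesical junctions. The stent is a straight rigid
tube (outer diameter Do = 2 mm, lumen Ds = 0.8 or 1 mm) resting on the
lower ureter wall, protruding s = 14.7 mm into each chamber, with eight
side holes (diameter D_SH) facing the stent–ureter gap, 35 mm apart, the
first centred at x = 12.8 mm.

The computational domain is the median (x–r) plane of this assembly. The
eccentric placement — stent touching the lower wall, a single extraluminal
channel of height 2 mm above it — is the only configuration consistent
with the coordinate conventions used throughout the package (lumen at
r ∈ [−1.5, −0.5] mm for Ds = 1 mm, side-hole channels at r ∈ [−t, 0] with
wall thickness t = (Do − Ds)/2). Side holes are rectangular slots, the 2D
trace of drilled cylindrical holes.

Working fluid: water-like urine analogue, ρ = 1000 kg/m³,
ν = 1.005 × 10⁻⁶ m²/s. Inlet: fully developed (parabolic) profile with
mean velocity 0.235 mm/s across the 30 mm chamber mouth, giving a total
flux Q0 = 7.05 mm²/s and an unstented-channel centerline velocity of
2.64 mm/s; channel Reynolds number ≈ 10.5, firmly laminar and steady.
Outlet: traction-free (static pressure ~0). All walls no-slip. Gravity,
peristalsis, wall elasticity and retrograde (vesicoureteral) flow are
outside the model.

### Chamber geometry (free parameters)

The junction chambers' exact shape is not constrained by the bench data
this model emulates. Defaults: symmetric trapezoidal expansion from the
4 mm channel to a 30 mm mouth — the mouth width is fixed by
Q0 / (inlet mean velocity) — over a cone length of 20 mm (> s, so the
stent tips float inside the chambers with fluid on all sides). Both are
`UreterSpec` fields. The luminal flux fraction and the end-hole flux/shear
magnitudes are the quantities sensitive to this choice (see Limitations).

## Discretization and solver

Taylor–Hood mixed elements on triangles: continuous piecewise-quadratic
velocity, piecewise-linear pressure (inf-sup stable; the velocity space
contains the Poiseuille parabola exactly, so the unstented base flow is
reproduced to solver precision). The mesh is block-structured: horizontal
material bands (chamber expansions, stent walls, lumen, side-hole band,
extraluminal channel) share a single graded streamwise grid, so every
fluid–solid interface lies exactly on grid lines; cells are classified by
band and split into triangles, and boundary facets are tagged
geometrically (inlet, outlet, ureter wall, stent outer/lumen walls, per-hole
walls).

Mesh sizes: `h_global` (streamwise, far from features; default 1 mm),
`h_sh` (inside and within 2 D_SH of each hole; default 0.05 mm), an
intermediate size near the stent tips and chamber junctions, and
transverse resolutions tied to these (≥6 rows across the lumen, ≥8 across
the extraluminal channel, ≥4 across the hole band). The defaults give
~30–45k elements (~200k unknowns) per case — the "desk scale" used by the
test suite and the acceptance script. A convergence study on this ladder
shows the side-hole fluxes converged to <1% and the luminal flux fraction
to ~0.1 percentage points; side-hole shear quartiles are converged to a
few percent (the medians' caveat is discussed under Limitations).

Nonlinear solution: initial Stokes solve, then Newton (an optional Picard
phase exists for robustness at higher Reynolds numbers), each step a
sparse-direct (SuperLU) solve of the coupled saddle-point system, iterated
until the nonlinear residual of the free unknowns drops by 1e-8. At
Re ≈ 10 this takes 2–3 Newton steps. The solver works in mm, s and
kinematic pressure (mm²/s²), which keeps matrix entries O(1); pressures
are converted to Pa on output. There is no randomness anywhere in the
mesh/solve/extract chain; repeated runs are bit-identical.

Mass conservation: the inlet/outlet imbalance is ~1e-7 relative on the
desk mesh; incompressibility holds weakly (per-element |div u| integrals
vanish under refinement, as for any Taylor–Hood discretization).

## Post-processing definitions

- **Side-hole flux**: V is sampled on the stent outer surface (r = 0 for
  the default geometry) over a ±1 mm window centred on the hole and
  integrated (Simpson, ≥200 points; wall segments contribute exactly zero
  by no-slip). Positive flux = out of the lumen. Normalized form
  Q̃ = ∫ (V/Uc) dx with Uc = 2.64 mm/s unless overridden.
- **Activation**: |Q_SH| > 0.2% of Q0, i.e. above the numerical-uncertainty
  level of the converged solution; configurable.
- **Luminal flux**: Q_i = ∫ U dr across the lumen opening at the stent
  inlet tip (x = −s).
- **Total exchange**: Q_t = Σ |Q_SH| (magnitude sum; the signed sum is ~0
  by mass conservation and carries no information about exchange
  capacity).
- **Wall shear**: τ = μ ∂V/∂x at both hole walls x = x_SH ± D_SH/2,
  one-sided second-order three-point differences into the fluid with step
  δ = D_SH/100 (exact for quadratic fields), evaluated at 50 uniformly
  spaced r per wall; the two walls' samples are pooled as magnitudes
  (their signed gradients are opposite, and the distribution of interest
  is the shear level). Quartiles are reported; distributions are compared
  with the two-sided Wilcoxon rank-sum test.
- **Base-flow errors**: ε_u = RMS(Ũ − Ũ*), ε_v = RMS(Ṽ) on normalized
  profiles sharing sample points; no silent regridding.

## Synthetic reference fields

The `synthetic` module supplies the closed-form flows the test suite uses
as oracles: plane/pipe Poiseuille profiles (exact flux and wall shear
rate), the annular Poiseuille profile (whose quadrature is the independent
check on the 0D flow-rate formula), raised-cosine crossflow bumps with
exact window integrals (compact support makes window-overlap behaviour
exactly testable), and seeded Gaussian perturbations for validating the
RMS error metrics. These fixtures expose the same `velocity(x, r)`
interface as a solved field, so the entire measurement chain runs
identically on analytic and computed flows. They emulate idealized
incompressible fields, not solver output: they carry no discretization
error, no corner singularities and no pressure field, so passing oracle
tests validates the extraction arithmetic, not the CFD accuracy.

## 0D hydraulics

The stent–ureter gap is idealized as a coaxial annulus. The analytic bulk
flow rate and the geometry factor ζ(D, Do) ∈ (1, 3/2) make the laminar
Darcy law f = 64ζ/Re_Dh exact (pipe limit ζ→1, f·Re = 64; thin-gap limit
ζ→3/2, f·Re = 96); the algebra is verified to machine precision by a
round-trip identity in the tests. Minor losses use the standard sudden
contraction/expansion coefficients at the lumen ends; the empirical
contraction constant defaults to c = 0.42 (textbook value for an abrupt
circular contraction; configurable, as no measured value is available for
this geometry). The stent-size sweep evaluates Q(Do)/Q(ref) at constant
pressure gradient and f(Do)/f(ref) at constant mean velocity — the two
natural normalizations for the two quantities. The pigtail scaling K ~
s/Ds is reported as a dimensionless number with an interpretation flag,
not fed back into the 2D model.

## Design choices on open points

- D_SH may exceed Ds (the bench's widest hole is 1.1 mm against a 1 mm
  lumen); hard errors only for geometrically impossible slots.
- Shear samples are magnitudes pooled over both walls (see above).
- Q_t uses the magnitude sum.
- The activation threshold is tied to the solution's uncertainty level
  rather than an absolute flux.
- Unstented convergence studies track the centerline velocity in place of
  the (undefined) side-hole metrics.

## Known limitations

- **2D median-plane model.** Out-of-plane transport is absent; fluxes are
  per unit depth (mm²/s). Conclusions are about trends and ratios, not 3D
  absolute values.
- **End-hole magnitudes depend on the chamber/tip geometry.** The flux
  through SH1/SH8 (and hence their shear level) is set by the pressure
  loss at the stent tips inside the junction chambers, whose true shape is
  a free parameter here. With the default chambers the luminal flux
  fraction is ~6.5–7.6% (Ds = 1 mm) and ~3.4–3.9% (Ds = 0.8 mm); the
  end-hole shear medians come out ~35–65% above the mid-hole levels that
  an identical-extraction reference reproduces closely. Mid-stent hole
  statistics (e.g. SH4: median 1.36 mPa, IQR 1.12–1.74 mPa at
  D_SH = 1 mm) are insensitive to this choice.
- **Median of a bimodal pool.** At the active end holes the pooled
  two-wall shear distribution is bimodal (the through-flow jet attaches to
  one wall); the median then sits near the gap between modes and is far
  more sensitive to geometry and sampling than the quartiles. Comparisons
  across hole sizes (ratios, rank-sum tests) are robust; single medians
  should be quoted with that caveat.
- **Sharp re-entrant corners.** Slot corners carry the usual Stokes-flow
  stress singularity; shear samples adjacent to corners grow slowly under
  refinement. Quartile statistics are stable against this.
- **Laminar, steady, Newtonian.** The solver warns above Re = 100; the
  model is not meant for turbulent or pulsatile regimes.
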