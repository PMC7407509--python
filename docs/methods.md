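# Methods

This note records the model, the closures, the numerical schemes and the
deliberate design choices behind `centrisim`, in the spirit of a solver
manual: enough detail to judge what a result does and does not mean.

## 1. Device and frame

Both units are planar microchannels of constant depth `H` etched on a
disk spinning at 500–3000 rpm (clockwise by default, i.e. the
angular-velocity vector points along −z for a disk in the x–y plane).
Each geometry lives in channel-aligned coordinates: `x` radially outward,
`y` azimuthal (lateral), `z` the depth.  The separator inlet sits 3 cm
from the disk center, the mixer 4.3 cm.  Channel curvature over the
~1–5 mm device extent (≤ a few degrees of arc) is neglected.

The carrier fluid is water (ρ_f = 1000 kg/m³, µ = 10⁻³ Pa·s); the
solute diffusivity is 1.67 × 10⁻⁹ m²/s; particles are rigid spheres of
1050 kg/m³.  Flow is laminar throughout (channel Reynolds numbers of
order 1–100); the solver warns if Re ≥ 2300.

### Geometry defaults (where the source material is silent)

The separator cross-sections are not published, so the package defines a
configurable default in the style of contraction–expansion-array (CEA)
sorters:

| parameter | default | note |
| --- | --- | --- |
| contraction | 50 µm wide × 200 µm long | square cross-section (H = 50 µm) |
| expansion | 250 µm wide × 400 µm long | **one-sided**: chambers bulge toward +y |
| repeat units | 8 | free parameter |
| collector → bifurcation | 105 µm wide, split at the midline | 5 µm septum, two 50 µm branches |
| target (CTC) outlet | the straight-wall (−y) side | see §4 |

One-sided expansions were chosen because they are the canonical CEA
layout and because they give the size-selective corner-lag mechanism of
§4; the straight wall runs along y = 0.

The mixer is a 100 µm × 50 µm channel of total centerline length exactly
2.5 mm: a 300 µm radial merge channel fed by the two inlets side by side,
then four azimuthal legs joined by radially outward risers (six 90°
corners).  The merge channel exists because a bare two-inlet face on an
azimuthal leg is starved by the centrifugal pressure gradient across its
own width (measured 40:1 inlet-flow imbalance); feeding radially splits
the streams symmetrically.  A serpentine that returns to its starting
radius has zero net centrifugal head, so every stage advances outward.
Obstacles are 40 µm squares attached to alternating side walls at
25/50/75% of each leg, clear of corners and of the outlet face (an
obstacle wake straddling the outlet cross-section corrupts the outlet
statistic).

## 2. Flow solver (reference backend)

The reference backend is a **2.5D depth-averaged plan-view solve** on a
uniform staggered (MAC) grid masked to the channel outline (default
spacing 5 µm, i.e. ten cells across the contraction width):

* momentum: semi-Lagrangian advection, implicit viscosity plus the
  shallow-channel wall drag `12 ν/H²` (exact for a parabolic depth
  profile), explicit centrifugal acceleration `ω² r` and lagged Coriolis
  `−2 ω × u`;
* incremental pressure projection with port-pressure Dirichlet ghosts
  (all ports at 0 gauge unless configured), so the steady state satisfies
  the discrete steady momentum equation exactly, independent of the
  pseudo-time step (5 × 10⁻⁵ s);
* convergence when the velocity change rate `|Δu|∞/(|u|∞ dt)` falls below
  0.05 s⁻¹ (configurable; the residual history is kept and a
  non-convergent solve raises).

Mass conservation is enforced to machine precision by the projection;
no-slip holds exactly on tagged wall faces.  Verified oracles: the
ω = 0 pressure-driven duct matches the closed-form cosh profile of the
depth-averaged equations to ~1–3% (first-order near-wall interpolation),
and the separate cross-section Poisson solve matches the rectangular-duct
Fourier series to < 1% in L2.  A full 3D solve of the
contraction–expansion array is outside this package's scope; the third
dimension enters through the closures below.

### Cross-gap closures

With `ζ = z/H` and depth-averaged plan velocity `ū`:

* axial profile `u(ζ) = 6 ζ(1−ζ) ū` (mid-plane factor 3/2);
* Coriolis secondary flow: solving
  `µ v″(z) = ∂p/∂y + 2 ρ ω u(z)` with no-slip walls and zero net lateral
  flux gives `v(ζ) = (12 ρ ω |ū| H²/µ) g(ζ)` along `ẑ × û`, with
  `g(ζ) = ζ²/10 − ζ³/6 + ζ⁴/12 − ζ/60`.  The mid-plane moves with the
  Coriolis force (peak `ρ ω |ū| H²/80µ`); fluid within ~0.27 H of either
  wall returns against it.  This is the reduced-backend "Dean drag"
  velocity supplied to particle tracking; it is *not* added to the
  resolved 2D field itself (zero depth average), avoiding double
  counting.

## 3. Force models

All evaluators are pure functions returning newtons.

* Stokes drag `3πµ d_p v_t`; Dean drag is the same law applied to the
  closure velocity above.
* Net centrifugal `−(ρ_p−ρ_f)(π d_p³/6) ω×(ω×r)` and net Coriolis
  `−(ρ_p−ρ_f)(π d_p³/3) ω×v_p` (the π d_p³/3 prefactor is 2 V_p — the
  Coriolis factor of two absorbed into the volume term).  Gravity is
  neglected: the disk is horizontal and the buoyant weight is ~10³ times
  smaller than the centrifugal force at 2000 rpm.
* Inertial lift in the correction-coefficient form
  `F_L = ρ_f U_max² d_p⁴/H² (C1 β² G1(s) + C2 β γ G2(s))` with the
  published (C1, C2) table at AR ∈ {1, 2, 4, 6}, piecewise-linear in AR
  and clamped (with a warning) outside [1, 6].

**Weighting functions.** G1(s) and G2(s) exist in the source literature
only as plotted curves, so the package ships a clearly labeled
*synthetic* surrogate (`data/lift_g_functions_synthetic.tsv`, version 2):
`G1 = e^(−s/0.08) − e^(−(1−s)/0.08)` (thin wall-repulsion boundary
layers) and `G2 = 11.216 [s(1−s)]³`, calibrated so that on a parabolic
profile the square-channel equilibria sit exactly at s = 0.2/0.8 and stay
off the walls (s* ∈ 0.12–0.2) for *every* tabulated aspect ratio — the
documented qualitative contract of the model.  (A first surrogate with
`G2 ∝ s(1−s)` violated that contract at AR ≥ 4, where the printed C2
jumps fourfold, driving equilibria into the wall-clearance clamp; the
steeper G2 is the fix.)  Users can load their own tables
(`LiftModel.from_tables`, PCHIP-interpolated).

**Per-axis superposition.** The 1D wall-coordinate formulation is applied
independently along the lateral axis (gap = local width, `s` from the
lateral walls, U_max from the mid-gap speed at the particle's depth) and
the vertical axis (gap = H, U_max = 3/2 the local plan speed), both with
the plane-Poiseuille `β = 4(1−2s)`, `γ = −8`.  Resolved velocity
gradients are not used for `β` at default resolution (ten cells across a
contraction make second derivatives noisy); the parabola is the
documented approximation.  Corner positions (both axes near their
equilibria) are artificially stable under this superposition — a known
artifact of any per-axis model.

The order-of-magnitude diagnostic (`force_ratio_report`) returns the
nondimensional groups `(ρ_p−ρ_f)H/(ρ_f d_p)`, `Hω/U_max`, `rω/U_max`,
`v_p/U_max` plus directly evaluated force ratios.  Note that with the
device's actual U_max the second group is ~10⁻²; the familiar "all of
the same order" argument holds only under the estimate U_max ≈ rω, which
the report makes explicit rather than asserting.

## 4. Particle tracking

Drag-implicit (semi-implicit) Euler: the Stokes relaxation time of a
10 µm cell (~6 µs) is far below the 50 µs reporting step, which makes
the equation of motion stiff; treating drag implicitly is unconditionally
stable and reproduces terminal velocities to < 0.1%.  Internally the
integrator substeps so no particle moves more than half a mesh cell
(2.5 µm) per substep; halving the reporting step then changes exit
positions by well under d_p/2.  Particles are one-way coupled (dilute
suspension), non-interacting, and tracked quasi-3D: plan position plus
depth, with the closures of §2 supplying the z-dependence.

Wall rule: a step that would cross a wall places the particle at the
d_p/2 clearance surface with the normal velocity zeroed (frictionless
sliding); axial blocking at a step face zeroes the axial velocity and
lets lateral drag carry the particle along the face.  Particles still in
transit at `t_max = 5 L/U_m` are reported `stalled` and count in the
efficiency denominator (conservative).  Seeding is uniform over the inlet
cross-section with d_p/2 clearance, initial velocity equal to the local
fluid velocity, reproducible for a fixed seed.  The study ensemble is
20 WBC (10 µm) + 20 CTC (20 µm); the three-population run uses
20/10/10 of 10/15/20 µm (counts unpublished; the 40-particle ensemble is
kept).

### How separation emerges in this model

Two size-selective mechanisms act together:

1. **Vertical lift focusing + secondary-flow return.**  Large particles
   migrate to the depth equilibria ζ* ≈ 0.2/0.8 within the array
   (migration per unit length ∝ u d_p³), where the Coriolis secondary
   flow runs *against* its mid-plane direction — both equilibria drift
   the particle toward the straight wall (−y).  Small particles stay
   distributed in depth and feel a near-zero (slightly +y) average.
2. **Corner lag at expansion mouths.**  The fan-out at a one-sided
   expansion is abrupt (the shallow-channel drag kills the jet within
   ~75 µm) while the reconvergence is gradual; a particle of relaxation
   time τ_p ∝ ρ_p d_p² lags the brief up-kick but follows the long
   funnel back, migrating toward the straight wall by O(τ_p u / unit).

Both rates grow with rpm (∝ ω² per unit length), which produces the
measured sweep shape (seed 1, default geometry): CTC efficiency 85% at
500 rpm (insufficient migration — particles follow their seeding
streamlines), 100% at 2000 rpm, 100% at 3000 rpm.  The model therefore
*saturates* above its focusing threshold instead of degrading at
3000 rpm: the real device's high-rpm breakdown (all particles
co-deflected onto one path) arises from restructured three-dimensional
secondary vortices that these closures do not represent.  Likewise, at
2000 rpm the 10 µm population is largely carried to the target side too
(WBC rejection is better at intermediate speeds): the desk model
reproduces the large-cell capture numbers and the low-rpm collapse, not
the simultaneous two-sided sorting.  Treat WBC-side results as
qualitative only.

## 5. Mixing

Steady convection–diffusion is discretized finite-volume on the flow
mesh: upwind convection with the full central diffusive conductance
retained on every face.  All coefficients are nonnegative, so a discrete
maximum principle holds (concentrations stay inside the inlet range); the
diffusive coupling also keeps closed recirculation zones (obstacle wakes)
nonsingular at high Péclet — a conductance-cutoff (hybrid/power-law)
scheme fails there.  Inlets impose Dirichlet values (0 sample side,
1 mol/m³ buffer side, diffusion at half spacing); walls are no-flux;
outlets are zero-gradient in both flow directions (treating outlet
backflow cells as no-flux instead implicitly injects clean fluid and
poisons the outlet statistic).  Solute conservation holds to ≤ 0.1% at
the operating point.

**Péclet-matched scaled-down mode.**  The physical channel Péclet
`U_m W/D ≈ 10⁴` cannot be transport-resolved on a desk mesh, so mixing
runs set an effective diffusivity `D_eff = U_m W / Pe_target` with
`Pe_target = 250` by default — large enough that the plain serpentine
stays visibly under-mixed over the 2.5 mm path (Pe ≈ 10 L/W), small
enough to be computable.  Because `D_eff` rescales with `U_m`, the same
Péclet holds at every rpm: rpm and obstacle contrasts reflect flow
topology, not the rescaling.  At this operating point the default 5 µm
mesh is part of the mode definition: upwind numerical diffusion
contributes to the effective transport, so the outlet quality shifts by
a few percent under refinement; in the transport-resolved regime
(Pe = 50, cell Péclet ~2) one refinement moves it by < 10⁻⁴ (tested).

**Statistics.**  Mixing quality is `1 − CoV` (CoV with the square root
and the N−1 normalization; the 0–1 range claimed for the index requires
the root), clamped to [0, 1] with clamping only ever triggered by
slightly-negative raw values at segregated stations.  Stations sample
N = 192 area-uniform points across the cross-section (the value beyond
which the statistic is flat; doubling N moves the outlet value by
< 0.5%).  Both the unweighted (area-average) and a flow-weighted
(mass-average) variant are computed, since the source description is
ambiguous; at the mixed outlet they agree to three decimals.

Measured at 2000 rpm, Pe_target 250 (values printed by the worked
example and the acceptance suite): obstacle mixer outlet
M.Q. = 0.999, plain serpentine 0.901; across 1000–2500 rpm the obstacle
mixer's outlet quality is minimal at 1000 rpm and nondecreasing above
it.  The obstacle gain comes from repeated stream thinning at the
40 µm constrictions (diffusion time ∝ striation width²), visible in the
per-station profile as jumps across each obstacle followed by dips at
the constriction itself (thin fresh striations), exactly the behavior a
CoV profile shows in obstacle mixers.

## 6. Determinism, degenerate inputs, tie-breaks

* The only randomness is inlet seeding (`numpy` PCG64, explicit seed);
  flow, concentration and integration are bitwise deterministic, so
  rerunning a scenario reproduces every report byte for byte.
* CoV is undefined for nonpositive mean or N < 2 (raised); M.Q. requires
  the station to intersect the fluid.
* Outlet assignment: first x-plane port crossed; the bifurcation label is
  decided by the particle's lateral position against the split
  coordinate.  Exactly-on-the-split particles go to the upper (waste)
  side (`y < split` is the target test).
* Zero-lift points (β = 0) are reported with an infinity flag in the
  force-ratio diagnostic rather than raising.
* AR outside the coefficient table clamps with a warning in direct calls;
  the tracker pre-clamps silently (documented here) to avoid per-step
  warning storms.

## 7. Known limitations

* No full 3D flow: cross-sectional vortex structure enters only through
  lubrication-type closures; phenomena driven by vortex restructuring
  (the high-rpm efficiency collapse, two-sided simultaneous sorting) are
  outside the model class.
* Per-axis lift superposition stabilizes corner equilibria that a true
  2D-cross-section lift map would not.
* The G1/G2 surrogate is synthetic; absolute lift magnitudes carry its
  uncertainty even though the (C1, C2) table is exact.
* First-order near-wall interpolation and upwind transport add numerical
  diffusion; at the scaled-down mixing Péclet the default mesh is part of
  the operating-point definition.
* Cells are rigid spheres: no deformability, no particle–particle
  interactions, no feedback on the flow.
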