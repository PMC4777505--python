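# Methods

## Model overview

`rfablate` simulates constant-power endocardial RF ablation with an
open-irrigated 8Fr electrode as a one-way-coupled electric–thermal–flow
problem:

1. **Quasi-static electrical problem.** At ~500 kHz cardiac tissue is
   predominantly resistive, so the RF field reduces to DC conduction,
   ∇·(σ∇Φ) = 0, with the generator voltage imposed on the metallic
   electrode surface, 0 V on the bottom boundary (the dispersive return
   electrode), and zero normal current elsewhere. The electrode interior
   (σ = 4.6×10⁶ S/m) is part of the solve; its surface is equipotential
   either way. Joule heating q = σ|∇Φ|² sources the thermal problem.
   Delivered power is computed as the volume integral of q (variationally
   more accurate than surface-current integration on coarse meshes) and
   impedance as Z = V²/P; half-model powers are doubled in 3D.

2. **Bioheat with phase change.** ∂(ρh)/∂t = ∇·(k∇T) + q − ρc **u**·∇T.
   Blood perfusion and metabolic heat are omitted: away from coronary
   vessels they are negligible during the tens of seconds of an RF
   application. The enthalpy derivative is the three-branch apparent
   capacity — ρ_l c_l = 3.30×10⁶ J m⁻³ K⁻¹ (liquid tissue),
   H_fg·C = 2.162×10⁹ × 0.75 J m⁻³ K⁻¹ over the 99–100 °C vaporization
   band, ρ_g c_g = 7.99×10⁵ (desiccated tissue). H_fg is stored
   volumetrically (2257 kJ/kg × 958 kg/m³); the tissue water content
   C = 0.75 multiplies it inside the plateau branch — the only reading
   under which the printed 2.162×10⁹ is arithmetically consistent.
   Myocardial σ(T) grows +1.5 %/°C to σ_o·2.5728 at 100 °C, drops linearly
   four decades over 100–105 °C (desiccation), then stays constant; the
   ramp is clamped below at the plateau value because the printed ramp and
   plateau coefficients disagree at exactly 105 °C by their rounding
   (3.0×10⁻⁴ vs 2.5728×10⁻⁴). k(T) grows 0.0012 W m⁻¹ K⁻² and plateaus
   above 100 °C. Property state is a pure function of the local
   temperature: tissue that cools below the band reverts to liquid-phase
   values (reversible by default; no hysteresis is modelled, and an
   irreversible-desiccation variant was considered out of scope for the
   present studies).

3. **Blood flow.** Steady incompressible Navier–Stokes with constant
   viscosity and no body forces. Nothing couples the flow back to the
   temperature field, so the velocity is solved once per configuration and
   frozen across the whole ablation (the driver asserts bitwise reuse).
   Saline irrigation enters through the hole band as a velocity inlet of
   magnitude Q/A along the outward electrode normal; the irrigation holes
   themselves are not meshed. The canonical band areas (6-hole ring
   1.32/0.77 mm², multi-hole surface 10.37/8.58 mm² for
   perpendicular/parallel contact) are half-model areas and always come
   from the lookup, never from the mesh, when converting a flow rate to a
   speed.

4. **PI power control.** e = P_target − P; V = clamp(Kp e + Ki ∫e, 0,
   V_max) with Kp = 4.78, Ki = 3.39 (units absorbed into the gains),
   V_max = 150 V, anti-windup freezing the integral during saturation.
   Power is measured *synchronously*: the voltage applied over a step is
   consistent with the power it delivers in that same step. Because the
   potential problem is linear, the within-step plant is exactly
   P = V²/Z with the current impedance, and the synchronous update is the
   closed-form positive root of (a/Z)V² + V − (aP_t + Ki I) = 0,
   a = Kp + Ki·dt. This matters: with these gains, the explicit update
   fed by the *previous* step's power is linearly unstable at dt = 0.05 s
   (loop gain ≈ −4.9), whereas the synchronous form settles smoothly and
   holds power within 3 % after ~4 s from a cold start. In a full run the
   integrator is seeded at √(P_target·Z₀)/Ki so the loop starts near its
   operating point.

5. **Lesion metrics.** The lesion is the connected component of
   {T ≥ 50 °C} in the tissue containing the hottest tissue node
   (disconnected satellite nodes are meshing artifacts and are excluded).
   Isotherm crossings are located by linear interpolation along mesh
   edges. D is the maximum depth below the tissue surface; MW the largest
   caliper diameter parallel to the surface (y-extent mirrored across the
   symmetry plane in 3D); DW its depth; SW the diameter of the surface
   intersection (0 when the lesion is detached from the surface, as
   happens under strong irrigation). LV is computed canonically by exact
   sub-cell integration of the indicator of the piecewise-linear field
   (cut simplices are decomposed into sub-simplices); a half-ellipsoid
   formula (2/3)π(MW/2)²D is available, clearly marked experimental, only
   for comparison with the formula-based volumes of the experimental
   literature.

## Geometry and meshing

The domain is an 80 × 80 × 40 mm blood box (half-model: y ≥ 0) over a
20 mm myocardial slab, chosen by the published chamber-convergence
criterion (<0.5 % change in peak tissue temperature after 60 s); the
`convergence_harness` reproduces that sweep protocol on any control
quantity. The electrode (8Fr = 2.667 mm diameter, 3.5 mm long,
hemispherical tip) is inserted 1 mm into the tissue by default; insertion
depth doubles as the contact-pressure surrogate (0.5–1.5 mm), and six-hole
configurations reject insertions beyond 1 mm, where the hole ring would
submerge. Internal dimensions that are not published are config-visible
assumptions: a 0.3 mm-radius, 1 mm-long thermistor bead starting 0.3 mm
above the tip apex, a catheter shaft of electrode diameter extending to
the chamber boundary, and a six-hole ring strip beginning 0.2 mm above the
hemisphere equator whose height is chosen so the strip area equals the
canonical ring area.

Meshes are graded structured simplex meshes (triangles in the
axisymmetric half-section, Kuhn-split tetrahedra in 3D): grid lines pass
exactly through every planar interface and band edge, spacing is
`min_size_at_interface` (default 0.2 mm, the published finest grid size)
near the electrode–tissue interface and grows geometrically (rate 1.25,
cap 4 mm), and nodes adjacent to the curved electrode surfaces are
radially snapped onto them, giving second-order interface geometry
(region volumes match CAD within 1 % at default resolution). On very
coarse grids the snap distance is capped and any snap that collapses a
cell is reverted, trading local surface smoothness for validity. Meshing
is fully deterministic.

Two build modes: `axisymmetric` (the (r,z) half-section of the
perpendicular configuration; seconds per simulated second) and `full3d`
(both orientations; the parallel electrode lies along +x with its shaft
extended to the outlet face). The axisymmetric mode cannot represent the
transverse 0.1 m/s blood stream; it forces that inflow to zero, stamps the
limitation into the flow metadata, and uses the lateral boundary as a
zero-traction outlet.

## Discretization and numerics

* P1 (linear) elements throughout; axisymmetric integrals use the 2πr
  Jacobian (centroid radius for stiffness — exact, since ∫r dA = A·r̄ —
  and exact linear moments in the pressure/divergence blocks, which keeps
  discrete mass conservation at machine precision).
* Thermal stepping: backward Euler with lumped mass, unconditionally
  stable at the default dt = 0.05 s (the published time step; halving it
  moves short-horizon peak temperatures by <0.5 %). The material
  nonlinearity is resolved by damped Picard iteration in which tissue
  capacities are *chords of the enthalpy curve*,
  (H(T_k) − H(T_n))/(T_k − T_n): this conserves latent heat exactly for
  elements crossing the vaporization band in one step and suppresses the
  branch-flipping oscillation of the raw apparent capacity. Steps whose
  iteration does not settle are halved up to three times, then accepted
  with a logged warning — the residual ringing localizes to one or two
  desiccation-front cells and does not move the 50 °C isotherm. Properties
  are evaluated at element midpoints. Advection (blood region only) uses
  streamline diffusion with the standard Péclet switch; the per-step
  energy report (stored enthalpy vs Joule input minus boundary and
  advective losses, boundary fluxes recovered from Dirichlet-row
  residuals) closes within 2 % throughout a run.
* Flow: equal-order P1-P1 with Brezzi–Pitkäranta pressure stabilization
  (δ = α h²/(4μ + 2ρ|u|h), α = 0.2 — calibrated once on the Poiseuille
  oracle, which the solver reproduces to 0.1 %) and Picard iteration with
  under-relaxation 0.9 (full steps near the fixed point). Nodal band
  Dirichlet data are scaled so the realized discrete saline influx equals
  the nominal u_s·A_band — without this, facets straddling the band edge
  leak up to ~60 % extra flux on the default coarse mesh; the scale tends
  to 1 under refinement. The Reynolds number (electrode diameter, fastest
  inlet; ~210 at 0.164 m/s) is reported per run to document the laminar
  assumption.
* Electrical: one unit-voltage solve per time step (the field is then
  rescaled exactly to the controller's voltage); sparse LU throughout.
* The lagged-σ re-solve option the design allowed was not implemented;
  the full re-solve is cheap at the problem sizes used.

## Problem sizes used

The test suite and the validation runs use the axisymmetric surrogate at
the published 0.2 mm finest grid size (~1.9 k nodes, ~3.5 k triangles;
a 30 s ablation ≈ 11 s wall time), which reproduces the validation-matrix
lesion depths within the ±0.5 mm experimental deviation scale. Full-3D
meshes from ~11 k nodes (1.4 mm) to ~42 k nodes (0.4 mm) are exercised
for geometry, impedance and flow properties; full-3D transient runs at
publication resolution are workstation-scale and are not part of the
default suite.

## What the surrogate does and does not show

The axisymmetric surrogate carries the complete physics of the
perpendicular configuration except the transverse blood stream. Lesion
depth is dominated by conduction into the tissue and is faithful (D within
±0.5 mm of the published 20/35 W validation values without any tuning).
Maximum width runs ~1–1.5 mm low, and the blood-pool peak temperature is
*overestimated*: with the far-field blood stagnant, the tissue-surface
blood layer outside the saline jet overheats (~80 °C at 35 W/30 s
irrigated, where the 3D chamber stays below 63 °C; the non-irrigated
axisymmetric case has literally no blood motion and is used only for
directional comparisons at short horizons). Trends — depth insensitive to
flow rate, surface width and blood temperature decreasing with flow,
lesion volume increasing with power and insertion depth, non-irrigated
blood hottest — are all reproduced with the correct sign.

## Known limitations

* Constant blood properties: no boiling or coagulation model in the blood
  pool; blood temperatures above ~100 °C in stagnant-blood surrogates are
  nominal model output, not physics.
* No tissue shrinkage, water transport, or electrode–electrolyte
  interface impedance; capacitive effects are excluded by the quasi-static
  limit.
* Contact pressure is represented purely by insertion depth; tissue does
  not deform.
* The published lesion-volume formula of the experimental literature is
  not reproducible from its citation; direct integration is canonical
  here, and formula-based comparisons should expect O(10–25 %)
  discrepancies on non-ellipsoidal lesions.
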