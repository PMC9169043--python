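# Methods

## Scope and idealization

The package studies blood stasis in occluded coronary arterial fistulas
(CAF) with terminal aneurysms on *idealized 2D geometries*.  Patient
anatomies are replaced by a parametric planar model: a straight parent
vessel (ascending aorta) of width `D_aorta`, a perpendicular fistula channel
of width `D_E` and total centerline length `L_F` whose last `L_A` is dilated
into a rectangular sac of width `D_MA` (the terminal aneurysm; an
`aneurysm_offset` parameter can make the sac eccentric), and small coronary
side branches.  All "volumes" are planar areas times a 1 mm out-of-plane
depth; all "wall areas" are arc lengths times the same depth.  The three
treatment variants differ only in the terminal segment:

- **untreated** — the distal fistula outlet is open (a `fistula_outlet`
  port, width `D_E`, at the bottom of the terminal segment);
- **aneurysm-reserved** (distal occlusion) — the outlet faces become wall;
  the sac stays as a blind pouch;
- **aneurysm-removed** (proximal occlusion) — the sac cells become solid,
  together with any branch that emerges from the sac.

Branch placement follows the surgical anatomy: occlusion is placed just
distal of the last coronary branch that must stay perfused, so the default
trunk branch arises along the distal course of the fistulous artery
(`along = 0.7`) and a second branch emerges at the aneurysm neck
(`along = 0.1` on the sac), where through-flow short-circuits and leaves the
sac interior stagnant.  The default parent-vessel diameter is 24 mm (adult
aortic scale, chosen to divide evenly by the standard grid spacings).

Rasterization snaps every physical dimension to a whole cell count once and
composes bands from those counts, so each region measure converges to the
analytic area at first order in the spacing and is exact for
grid-commensurate dimensions.  Construction enforces a resolution floor of
8 cells across `D_E` and validates 4-connectivity of the fluid region.

## Inlet waveform and 0D outlet models

The inlet volumetric flow is periodic (period 1 s): a half-sine systolic
pulse of duration `systolic_fraction × period` (default 0.35) over a
diastolic plateau, renormalized so the cycle mean is exactly `Q_mean`;
`pulsatility` (default 3.0) is the peak-to-mean ratio.  The exact published
literature curve is not reproduced; all downstream quantities depend on the
cycle mean and the oscillatory envelope, not the precise shape.

Outlets are 0D models receiving the instantaneous outflow `Q` and returning
a pressure:

- **Windkessel RCR** (aortic and fistula outlets):
  `C dP_c/dt = Q − P_c/R_d`, `P = P_c + Q R_p`, with `R_p = 0.09 R_total`,
  `R_d = 0.91 R_total`, `C = 0.001 cm⁵/dyne = 10⁻⁸ m³/Pa`.
- **Coronary LPN** (coronary outlets):
  `C_a dP₁/dt = Q − (P₁−P₂)/R_am`,
  `C_im d(P₂−P_im)/dt = (P₁−P₂)/R_am − P₂/R_v`, `P = P₁ + Q R_a`,
  with venous pressure 0.  The intramyocardial pressure `P_im(t)` is a sin²
  systolic bump peaking at 16 kPa, scaled 1.0 for left and 0.5 for right
  coronary beds.  Element values are not published; the splits
  `R_a:R_am:R_v = 0.32:0.52:0.16` of the published per-outlet `R_total`,
  `C_a = 10⁻¹⁰`, `C_im = 10⁻⁹ m³/Pa` follow standard coronary-LPN practice.
  With constant `P_im` the steady state of this topology is
  `P = Q(R_a+R_am+R_v)`; `P_im` acts transiently (systolic impediment).

All 0D states advance by backward Euler.  For every model the implicit step
yields an affine relation `Q = gP − h`, which is used in two places: the
pure-0D flow-split solver (`solve_0d_flow_split`) closes a common pressure
node exactly per step, and the 2D solver couples outlets to the pressure
projection without any relaxation loop (below).  The 0D flow split
initializes each outlet at the steady resistive division of the mean flow —
coronary charging time constants reach hundreds of seconds, so a cold start
would converge cycle-to-cycle while still far from the operating point.

## Flow solver

Staggered (MAC) finite volumes on the uniform grid; face-normal velocities,
cell-centered pressure.  Spatial terms: second-order central diffusion and
van Leer flux-limited second-order upwind advection.  Time integration is
BDF2 (backward Euler on the first step) at `dt = 5–10 ms`:

1. **Predictor.**  `(I − coef·ν∇²) u* = BDF2 history − coef·N(u⁽ᵐ⁾) − ∇ψ_prev`
   with prefactorized sparse Helmholtz operators per component; no-slip
   enters through ghost reflection, the inlet through the prescribed
   parabolic profile scaled to `Q(t)`.
2. **Incremental pressure projection.**  The projection solves for the
   pressure *increment* (the previous step's gradient already acts in the
   predictor).  This matters: a non-incremental projection feeds the full
   pressure gradient through the predictor's wall boundary condition and
   contaminates the near-wall momentum balance (observed as a 27% wall-shear
   error before the switch; 0.8% after).
3. **Exact 0D coupling.**  The projection is linear in the outlet Dirichlet
   pressures and each outlet is affine in its flux, so the coupled
   pressure/0D system reduces to a small linear solve over precomputed
   unit-pressure port responses — solved exactly every sub-iteration.
4. **Picard sub-iterations** (cap 50, RMS increment tolerance 10⁻⁵ of the
   peak inlet velocity) update the advecting field; at the fixture CFL
   numbers (< 0.7) they converge in a handful of iterations.

Global mass conservation is enforced by the projection to solver round-off
(measured residuals ~10⁻¹³ of peak inlet flow).  Cycles repeat until the
cycle-to-cycle RMS velocity change falls below 0.5% (a criterion chosen
here; the default cap of 10 cycles reflects the typical transient set by the
aortic Windkessel time constant `R_d C ≈ 2.1 s`; the standard fixture
converges in ~8).

Wall shear is extracted per wall face as `τ = μ ∂u_t/∂n` from a one-sided
quadratic through the first three fluid cell-center tangential velocities.
Not anchoring the fit at the wall makes it exact for the discrete parabolic
profile including the O(h²) near-wall offset of the staggered no-slip ghost;
measured plane-Poiseuille errors are 0.78% at 16 cells across the gap and
0.19% at 32 (second order).  The sign convention is a fixed global tangent
(+x for horizontal walls, +y for vertical), giving opposite signs on
opposite channel walls; TAWSS and OSI are invariant to it.

Fixture Reynolds numbers are kept near 300 in the parent vessel (laminar)
by the choice `Q_mean = 10⁻³ m³/s` per metre of depth.  Clinical-scale CFD
of these anatomies runs RANS turbulence models on 3D patient
reconstructions; replacing that regime with laminar 2D flow is a deliberate
desk-scale substitution whose consequences are discussed under
*Limitations*.

## Washout (two-fluid stasis model)

Because the two fluids share all material properties and surface tension is
zero, two-fluid volume-of-fluid transport is mathematically identical to
conservative passive advection of the old-blood fraction α, and the fraction
cannot alter the momentum solution — so the converged periodic cycle is
replayed (a fully coupled mode would only re-solve identical equations).
α is initialized to 1 over the whole domain (aorta included) and every
port admits α = 0 on inflow.

The advection scheme is Zalesak flux-corrected transport: first-order upwind
low-order fluxes plus van Leer-limited high-order corrections, limited so α
stays in [0, 1] to round-off at every step (a raw dimension-split MUSCL
scheme is *not* bounded for 2D divergence-free fields, which is why FCT was
chosen).  Each flow step is sub-stepped to a scalar CFL of 0.4.  On the
128-cell plug-flow oracle the channel-mean fraction tracks
`max(0, 1 − Ut/L)` to round-off until the smeared front reaches the outlet.

OBVF is reported per cardiac cycle; washout stops when OBVF has dropped by
less than 1 *absolute* percentage point over the trailing 10 cycles (the
relative reading diverges as OBVF → 0), with a 60-cycle cap and a warning.
On the standard fixture the occluded variants are still draining slowly at
the cap; the reported values are the 60-cycle OBVFs.

## Metrics and decision rule

TAWSS and OSI use the standard definitions (the trapezoid rule on the
uniformly sampled periodic cycle reduces to the sample mean).  Thresholds:
OSI > 0.3, TAWSS < 10 dyne/cm² (= 1 Pa).  Threshold areas default to the
fistula-wall scope (faces whose adjacent fluid cell is tagged fistula or
aneurysm) because fistula thrombosis is the quantity of interest; the
whole-wall scope is available.  OBV = OBVF/100 × fistula measure, where the
fistula measure includes the aneurysm (the published convention
V_F ⊃ V_A).

The occlusion recommendation is a pure function of the comparison: relative
OBV difference ≥ 50% → proximal; below, V_A/V_F < 0.25 → either, else
distal.  Both cutoffs are this package's formalization of published
narrative (no numeric thresholds are published there) and are exposed as
parameters; the morphology default 0.25 sits between the published case
ratios 0.028 and 0.348 that anchor the two narrative outcomes.  D_E > 8 mm
sets the guideline anticoagulation flag.

## Standard fixture and problem sizes

The default configuration (`fistulaflow.pipeline.default_config`) uses the
published case-1 shape family scaled to the grid: D_E 16, L_F 80, D_MA 40,
L_A 32, D_aorta 24, L_aorta 160 mm at 1.5 mm spacing (≈ 7100 cells, ≈ 2800
fluid), dt 5 ms (200 steps/cycle), warm-up cap 10 cycles, washout cap 60
cycles.  Outlet resistances are the published case-1 column (aorta 2.3171·10⁸,
fistula 6.8721·10⁸, coronaries 6.2281·10⁹ and 1.2908·10¹⁰ Pa·s/m³).  A full
three-variant run takes ≈ 2 minutes on one CPU.  Verification fixtures
(plane Poiseuille, plug flow) use channels of 16–32 cells across and, for
fast steady states, elevated viscosities — the analytic solutions they are
checked against hold for any viscosity.

## What the synthetic generator does and does not emulate

It emulates: the published morphology parameters (entrance diameter, fistula
and aneurysm lengths and diameters, fistula ⊃ aneurysm volume convention),
the three treatment variants including which structures each occlusion
excludes, the published outlet resistances and compliance, the fluid
properties, the pulsatile single-second cycle, and the washout protocol.

It does not emulate: 3D anatomy (tortuosity, entrance angle, eccentric
lumens), turbulence in the aorta, vessel-wall compliance, non-Newtonian
rheology, or patient-specific inlet waveforms.  Consequently, passing tests
show that the *mechanisms* — blood stealing corrected by occlusion, stasis
concentrated in the dead-ended distal fistula and retained sac, the
volumetric OBV metric separating the two occlusions — are reproduced; the
clinical-scale magnitudes (absolute OBVs, flow-split percentages, high-OSI
extents) reported for patient anatomies are not desk-reproducible and are
not claimed.

## Known limitations

- **OSI extent in the stagnant sac.**  At desk-scale laminar Reynolds
  numbers the retained sac hosts a directionally stable, Stokes-like gyre:
  wall shear there is tiny (captured by the low-TAWSS metric) but does not
  reverse, so OSI > 0.3 marks only isolated separation points rather than
  the broad distal-fistula patches seen with turbulent 3D anatomy.  The
  high-OSI *area* still ranks the occlusions correctly on the standard
  fixture, but the high-OSI *proportion* does not (the reserved variant's
  wall-area denominator is about twice the removed variant's), so the
  proportion is the least transferable of the four metrics in this
  idealization — consistent with it also being the least discriminating
  metric in the clinical comparison.
- Stasis is the only element of Virchow's triad modelled; no thrombus
  formation kinetics, platelet activity or coagulation chemistry.
- Rigid walls: an occluded fistula stores no net volume over a cycle, so
  entrance fluxes of dead-end variants integrate to zero; compliant walls
  would admit small oscillatory storage.
- The washout cap (60 cycles) can truncate slow sac drainage; reported
  OBVFs of the occluded variants are cap values, flagged by the
  convergence boolean in every report.
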