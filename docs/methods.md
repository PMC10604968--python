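# Methods

## Model overview

`ipchemo` simulates drug delivery to a vascularized peritoneal tumor
nodule during intraperitoneal (IP) chemotherapy. The nodule is a 2D
ellipse (default semi-axes 2.425 mm × 1.755 mm, i.e. full axis lengths
4.85 × 3.51 mm) containing an explicitly resolved vessel network. The
simulation has two phases, matching the physics' separation of time
scales:

1. **Steady fluid flow.** Blood flows through the lumens (laminar Stokes
   flow, prescribed pressures of 25 mmHg at inlets and 10 mmHg at
   outlets, no-slip walls). The interstitium is a porous medium obeying
   Darcy's law `v_i = −K ∇P_i` with steady continuity `∇·v_i = φ_B − φ_L`,
   where the transmural Starling exchange is
   `φ_B = L_p (S/V) (P_B − P_i − σ_s (π_B − π_i))` and lymphatic drainage
   `φ_L = 0` (tumors lack functional lymphatics). The interstitial
   pressure (IFP) is pinned to 0 at the tumor surface.
2. **Transient drug transport.** With the flow frozen, free Doxorubicin
   obeys a convection–diffusion–reaction equation with transvascular
   exchange; bound and internalized drug follow first-order binding
   (`K_ON C_rec`, `K_OFF`) and cellular uptake (`K_INT`) kinetics. During
   IP dosing the plasma concentration is zero, so the vessels act purely
   as localized drug sinks while drug enters across the tumor surface,
   where the free concentration is held at the exterior bath value
   (0.8 mol/m³ for the one-hour scenario; 45 µM over six hours in the
   validation-style scenario, both expressible via config).

Treatment efficacy is summarized by the AUC of the mean free-drug
concentration (mol·m⁻³·s), the half-width penetration depth W₁/₂ (depth
at which free drug falls to half the exterior concentration, evaluated
from both ends of four sampling axes), and the fraction of killed cells
`FK = 1 − exp(−ω·C_I)` with ω = 0.6603 m³/mol.

## Vessel-exchange coupling modes

The tabulated physiology fixes a constant vascular pressure
P_B = 2100 Pa, while the lumen boundary conditions impose 3333/1333 Pa at
the terminals. Both readings are implemented:

* `distributed` — φ_B acts as a volumetric source everywhere with the
  constant P_B; no lumens are needed. On a disc of radius R this has the
  closed form `P(r) = P_e [1 − I₀(αr)/I₀(αR)]` with
  `α = √(L_p (S/V)/K)` and `P_e = P_B − σ_s(π_B − π_i) = 1470 Pa`, which
  is the primary verification oracle (center value ≈ 1457 Pa at
  R = 1.755 mm).
* `wall_coupled` (default for image-based runs) — lumens are meshed, the
  Stokes solve supplies the local intravascular pressure, and the
  exchange is a vessel-wall Robin flux `L_p (IBP − P_i − σ_s Δπ)` per
  wall area (S/V does not enter; the wall area is explicit). Only this
  mode can raise IFP above the 1470 Pa distributed-mode ceiling, which is
  what an image-based vasculature with 25 mmHg feeding pressure produces.

In `wall_coupled` transport the drug exchange is the wall-localized
analogue of the transvascular solute law: flux
`J_v (1−σ_f) C_P + P (C_P − C_F) · Pe/(e^Pe − 1)` per wall area with the
facet-local Péclet number `Pe = J_v (1−σ_f)/P` built from the steady
transmural fluid flux `J_v`. The factor `Pe/(e^Pe − 1)` is evaluated by
series below |Pe| < 10⁻⁶. In `distributed` transport the volumetric form
with `Pe = φ_B(1−σ_f)/(P S/V)` is used.

## Parameters

All internals are SI; concentrations are mol/m³ (1 M = 10³ mol/m³), so
the binding rate 1.5×10² M⁻¹s⁻¹ becomes 0.15 m³·mol⁻¹·s⁻¹ and
C_rec = 10⁻⁵ M becomes 10⁻² mol/m³. Defaults (config-overridable, with a
`{value, units}` form accepting mmHg, cm²/s, µM, …):

| symbol | meaning | default (SI) |
|---|---|---|
| K | interstitial hydraulic conductivity | 3×10⁻¹⁴ m²/(Pa·s) |
| L_p | vessel-wall hydraulic conductivity | 2.1×10⁻¹¹ m/(Pa·s) |
| S/V | vessel surface density | 2×10⁴ m⁻¹ |
| P_B, π_B, π_i | vascular / osmotic pressures | 2100, 2700, 2000 Pa |
| σ_s | osmotic reflection coefficient | 0.9 |
| D_F | Doxorubicin diffusivity | 3.4×10⁻¹⁰ m²/s |
| P | vessel-wall drug permeability | 3×10⁻⁶ m/s |
| K_ON·C_rec, K_OFF, K_INT | binding / unbinding / uptake | 1.5×10⁻³, 8×10⁻³, 5×10⁻⁵ s⁻¹ |
| φ | accessible volume fraction | 0.3 |
| ω | kill-law constant | 0.6603 m³/mol |
| μ | blood viscosity (lumen solve only) | 3×10⁻³ Pa·s |

Decisions where the physiology tables are silent:

* The printed 4.85/3.51 mm are read as **full axis lengths** (semi-axes
  2.425/1.755 mm); a config key `axis_lengths_mm` accepts the full-length
  form, `semi_axes_mm` the semi-axis form.
* σ_f (drug filtration reflection) is untabulated; default σ_f = σ_s = 0.9.
* Blood viscosity is untabulated; 3×10⁻³ Pa·s (tumor microvascular blood),
  config-exposed. It only scales lumen velocities, not pressures.
* The unbinding term: the free- and bound-drug equations are only
  mutually consistent (drug-mass conserving) if unbinding returns drug to
  the free pool, i.e. reaction `−(K_ON C_rec C_F − K_OFF C_B)/φ` in the
  free-drug equation. That is the default; `legacy_unbinding_sign=True`
  switches to the variant with `+K_OFF C_B` inside the subtracted bracket
  for sensitivity studies (it strictly loses mass, as a test asserts).

## Discretization and numerics

* **Mesh.** Conforming P1 triangles over both tissue and lumens,
  generated in-package: a structured band of quad-split layers hugs the
  tumor surface (default 21 layers, geometric growth 1.2, spanning 10% of
  the minor semi-axis — auto-shrunk, and logged, when vessels approach
  the surface), graded offset point rings wrap the vessel walls (default
  6 rings; point-graded rather than quad-structured so concave branch
  junctions stay meshable), and the remainder is a Delaunay triangulation
  of graded point sets. Mesh area matches the geometry within 0.5%;
  free-triangle minimum angles are checked against a configurable floor.
  Element counts are config-driven with refinement checks rather than
  fixed, since mesher-specific counts are not reproducible.
* **Stokes (lumen) solve.** Equal-order P1–P1 with Brezzi–Pitkäranta
  pressure stabilization (β = 0.1, h²/μ scaling); no-slip walls,
  prescribed-pressure "do-nothing" traction at the terminal caps. On a
  straight channel this reproduces plane Poiseuille flow (centerline/mean
  speed 1.5 within 1%, linear pressure) and terminal fluxes integrate to
  a net imbalance at rounding level when evaluated by exact P1 edge
  quadrature of the nodal velocity.
* **Darcy solve.** Sparse SPD direct solve; the discrete relative
  residual is checked (default 10⁻¹⁰, far below the 10⁻⁴-type reduction a
  stationary iterative scheme would target). Boundary fluxes are
  recovered consistently from the Dirichlet-row residuals, so the global
  fluid balance (wall influx = surface outflow) closes to machine
  precision by construction and is asserted at 1% in tests.
* **Transport.** First-order IMEX with lumped mass: implicit diffusion,
  binding-on and vascular exchange; explicit advection (Galerkin, cell
  Péclet ≪ 1 at the default resolution) with a CFL guard that raises an
  `unstable-step` error; the bound/internalized pair advances by the
  *exact* closed-form propagator of its 2×2 linear system with the
  free-drug value frozen over the step (this is what lets the kinetics
  verification hold to 10⁻⁶ over an hour). Default dt = 1 s. A per-step
  mass audit (surface influx + vascular exchange + advective term vs.
  total-mass change, all evaluated at the scheme's own time levels)
  accumulates in the solver; its worst relative closure defect is ≲0.3%
  at dt = 1 s and is first-order in dt (the implicit free-drug reaction
  vs. exact kinetics propagator mismatch).
* **Metrics.** Spatial means are area-weighted over tissue only (lumens
  excluded). Axis profiles use linear interpolation on the tissue
  triangulation; samples inside lumens are flagged. W₁/₂ is the first
  linear-interpolated crossing of half the exterior concentration from
  above; a profile that never crosses reports the "no-crossing" signal
  (None), not an error. AUC uses the trapezoidal rule; its unit is that
  of a concentration–time integral, mol·m⁻³·s.

## Image processing

Micrograph segmentation is: optional light Gaussian smoothing (σ = 1 px),
global histogram equalization for contrast normalization, thresholding,
connected-component filtering by minimum area, sub-pixel contour tracing
at the half level, and light Douglas–Peucker simplification (0.2 px) —
the mesher resamples wall polylines anyway. One detail: a globally
equalized image has a flat histogram, on which Otsu's criterion
degenerates, so the Otsu partition is computed in the (smoothed) original
intensity domain and carried through the monotone equalization — the
same partition, but robust (Dice ≥ 0.98 against ground truth on noisy
synthetic renders at noise σ = 0.1). A fixed-threshold policy on the
equalized image is available as fallback. Inlet/outlet terminals on a
segmented image cannot be detected reliably and are supplied as config
points snapped to the nearest lumen boundary.

## The synthetic vessel fixture

The reference micrograph behind the published geometry is third-party
material and is not bundled, so the package generates a synthetic stand-in
with the features the model exercises: a branched channel tree with five
inlet and six outlet terminals near (never crossing) the ellipse
boundary, terminals on the left/right halves respectively, uniform
channel width 0.05 mm, seeded jitter for irregularity, dilated from a
two-hub polyline tree. It is deterministic per seed and round-trips
through rasterization and re-segmentation within 10% in area.

What it does **not** emulate: the capillary density of real tumor
vasculature. The tabulated S/V = 2×10⁴ m⁻¹ corresponds to roughly 270 mm
of vessel wall in this cross-section; the 11-terminal tree provides an
order of magnitude less. Consequently the vessel-sink effect is weaker
and drug penetrates deeper than in a real densely vascularized nodule:
on the fixture the one-hour run yields W₁/₂ ≈ 0.3–0.6 mm, mean IFP
≈ 600 Pa and AUC ≈ 1000 mol·m⁻³·s, versus ≈ 0.11–0.14 mm, 1433 Pa and
295 mol·m⁻³·s reported for a real micrograph-derived geometry. Passing
tests therefore demonstrate correct physics (oracle agreement,
conservation, the right inequalities: interior-peaked IFP, surface-confined
drug, vessels as sinks, axis-dependent penetration), not a reproduction of
any particular tumor's numbers, which are conditioned on its vasculature.

A further note on the kill fraction: with the tabulated kinetics the
internalized pool after one hour is bounded by
`K_INT · ∫C_B dt ≲ 5×10⁻⁵ × 3600 × C_B ≈ 0.01–0.02 mol/m³`, giving
FK of order 10⁻²; an FK near 0.2 would require a mean C_I ≈ 0.35 mol/m³,
which those constants cannot produce in an hour from a 0.8 mol/m³ bath.
The package reports what the stated kinetics yield.

## Problem sizes and runtimes

Default pipeline meshes are ~28k nodes / ~55k triangles (h_interior
0.08 mm, 21 surface layers, wall spacing = channel width/4); the steady
solves take ~25 s and the hour-long transport phase ~50 s at dt = 1 s on
one CPU. The test suite uses coarser fixtures (10-layer bands,
h_interior 0.1 mm, shorter horizons) chosen so each oracle still meets
its stated tolerance; the disc oracle mesh (h = 0.05 mm) achieves 0.1%
L∞ against the Bessel closed form, an order below the 1% gate.

## Known limitations

* 2D cross-section; no out-of-plane transport.
* Static vasculature, Newtonian blood, rigid walls; no vessel compliance
  or remodelling.
* Uniform transport properties in tissue; no necrotic-core segmentation.
* Constant exterior bath concentration (no peritoneal pharmacokinetics).
* First-order time integration; Galerkin advection without stabilization
  (adequate at the interstitial velocities involved, ≲ µm/s).
* No drug metabolism, multi-drug interaction, or thermal effects.
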