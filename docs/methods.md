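# Methods

`alveoflow` models blood flow through the capillary network of a single
pulmonary alveolus and uses it in two directions: forward (geometry →
hemodynamics → gas exchange) and inverse (hemodynamic observations →
plausible arteriole/venule configurations).  This note records the model,
its assumptions, the parameter choices, and the numerical decisions.

## Geometry

**Alveolar base.** The alveolus is a sphere of radius R truncated by the
plane of the alveolar mouth (a circular opening of radius a).  With the
mouth normal along +z, the mouth plane sits at z_m = √(R² − a²) and the
air space is the larger spherical segment of depth R + z_m.  Two
constructions are provided: from the alveolar diameter (R = d/2) and from
the alveolar volume, where R solves V = (π/3)·depth²·(3R − depth) by a
bracketed Brent root solve (relative tolerance 1e-10; the segment volume is
strictly increasing in R at fixed mouth radius).  Defaults: diameter 225 µm
or volume 4.6×10⁶ µm³, mouth 181 µm.

**Capillary sheet.** The capillary bed is a sheet: two endothelial layers a
height h = 6.34 µm apart, held open by tissue pillars of diameter
d_p = 3.1 µm spaced s = 6.17 µm apart (pillar/gap ratio ≈ 0.5).  Pillars
are not meshed individually (~1,450 of them); they are homogenized into a
plan-area fraction φ = (π/4)·d_p²/(s + d_p)² ≈ 0.088 for the default square
lattice (hexagonal packing is available) and a friction factor f (below).
The sheet mid-surface is a sphere of radius R + h/2; the offset from the
epithelial surface is configurable because no measurement pins it down.

**Holes.** The mouth, 17 pores of Kohn (12.3 µm), and the vessel ports are
circular holes in the sheet.  Pores are placed by seeded rejection sampling,
uniform over the closed surface, with non-overlap constraints, full
clearance below the mouth rim, and a buffer of one port radius around every
vessel.  All randomness flows from explicit integer seeds; geometry
generation is bit-reproducible, and mirrored replicates are exact
reflections (triangle areas agree bitwise).

**Vessel placement.** The default configuration is one 20-µm arteriole at
azimuth 0° on the sphere equator and one 20-µm venule opposite at 180°.
When a configuration has several vessels of one type, they form a compact
stack along the meridian of their azimuth (spacing 2.8 port radii,
symmetric about the equator).  We also evaluated fanning the vessels in
azimuth over wide bands; with fans, edge-of-band arteriole–venule pairs come
within ~60° of each other, flow short-circuits around the rim, and the model
loses the linear velocity–area relation and the ~4× speed scaling of the
four-vessel configuration that it exhibits with antipodal supply and
drainage.  The meridional stack keeps every arteriole roughly opposite
every venule and was frozen as the default.

**Triangulation.** The mid-surface mesh starts from an icosphere whose
subdivision level matches the requested edge length (default 4 µm, ~16k
triangles, ~8k nodes).  For every hole, vertices within half an edge of the
rim circle are snapped onto it, triangles inside the hole are removed, and
the interior is relaxed by 8 rounds of Laplacian smoothing (rim vertices
fixed, vertices re-projected to the sphere).  The carved area agrees with
the spherical-cap closed form to well under 1% at the default resolution and
converges to it at first order or better under refinement.  A hole needs
roughly three mesh edges across its diameter; the pore diameter therefore
bounds the coarsest usable resolution (edge ≤ pore diameter/3).

**Morphometric outputs** use the analytic closed forms (segment volume,
mouth area, lateral area 2πR·depth minus pore discs).  Capillary volume is
open_area·h·(1 − φ); the gas-exchange surface is the inner endothelial
layer, open_area·(1 − φ); the total capillary surface adds the outer layer
and the pillar side walls.

## Sheet-flow solver

At alveolar scale the flow is deep in the Stokes regime (Re ≈ 0.0076 with
ρ = 1,050 kg/m³, v = 2.3 mm/s, and the capillary sheet height 6.3 µm as the
characteristic length) and h ≪ R, so the steady incompressible equations
reduce to the lubrication (Hele-Shaw) closure on the mid-surface:

    ∇s·(T ∇s p) = 0,   T = h³(1 − φ)/(12 µ f),   u = −h²/(12 µ f)·∇s p.

This thin-film reduction is the package's central desk-scale substitution
for volumetric CFD; absolute pressure-drop levels inherit its bias (see
Limitations).  Gravity is neglected: the hydrostatic variation over ~200 µm
(~2 Pa) is two orders of magnitude below the simulated driving pressure.
Walls are rigid; the top and bottom sheet plates are no-slip (that is what
the h³/12 transmissivity encodes); hole rims other than ports are zero-flux.

**Boundary conditions.** Each arteriole imposes a volumetric influx
Q = v_in·π(d/2)² distributed uniformly along its rim (v_in = 2.3 mm/s);
venule rims hold the outlet pressure (1,127 Pa).  Arterioles and venules
continue as straight Poiseuille tube stubs of 100 µm (configurable) whose
losses 32µLv/d² are added analytically on both sides, so the reported Δp
runs between the far (tube) ends of the vessels, where a pressure
measurement would sit.

**Discretization.** Piecewise-linear finite elements on the triangulated
surface (per-triangle transmissivity), assembled to a symmetric
positive-definite sparse system and solved by direct factorization
(iterative CG with 1e-12 tolerance as an option).  Global mass balance
closes to ~1e-12 relative; the discrete maximum principle holds on the
near-equilateral carved meshes.  The flat-strip benchmark reproduces the
plane-Poiseuille closed form to machine precision, because the exact
solution is linear in x.

**Friction factor.** Pillar drag beyond the area blockage is calibrated by
a resolved unit-cell problem: the thin-film pressure equation on one square
cell with the pillar disc as a zero-flux hole (finite volumes, harmonic face
transmissivities, 161² cells), driven by a unit pressure drop.  The
calibrated default is f = (1 − φ)·T0/T_eff ≈ 1.09 for the default lattice,
consistent with the dilute-limit potential-flow result T_eff/T0 ≈
(1 − φ)/(1 + φ).  Modes: unity, calibrated, or a user-supplied number.
This 2-D cell problem ignores the no-slip sides of the pillars, so f is a
lower bound on the true three-dimensional pillar drag.

**Carreau rheology.** η(γ) = η∞ + (η0 − η∞)[1 + (λγ)²]^((n−1)/2) with
η0 = 56 cP, η∞ = 3.5 cP, λ = 1.902 s, n = 0.3568.  The effective shear rate
in the sheet is the plane-Poiseuille wall shear γ = 6|u|/h (8v/d inside
tube stubs).  Picard iteration on the per-element viscosity with
under-relaxation 0.5 runs until the maximum relative change of |u| drops
below 1e-5 (typically ~18 iterations).  Because the arterioles impose
fluxes, the velocity field is nearly independent of the viscosity field;
Newtonian and Carreau mean speeds agree within a fraction of a percent,
while the Carreau pressure drop is about twice the Newtonian one (bulk
shear rates ~300 s⁻¹ put the apparent viscosity near 4.3 cP against the
2 cP Newtonian value).

**Measurements.** Mean capillary speed is the mass-weighted average of the
depth-averaged speed over sheet elements (weights ρh(1 − φ)A).  Pressure
drop is the flux-weighted mean arteriole rim pressure plus arteriole stub
losses, minus the outlet pressure corrected by the venule stub losses.
Position speeds report inlet (= v_in), a near-arteriole band (elements
within 1.5 port radii of the rim), the center (farther than 3 port radii
from every port), a near-venule band, and the outlet (flux/area at the
venules).

## Tube-flow network

The alternative capillary concept is a graph of cylindrical segments
(diameter 6.31 µm, target length 5.75 µm) built from the edges of a
quasi-uniform triangulation of the closed base surface, with Hagen-
Poiseuille conductances g = πd⁴/(128µL) and Kirchhoff conservation at the
nodes; ports attach to their three nearest nodes to avoid point-source
singularities.  Replicates differ by a seeded rotation of the triangulation
about the mouth axis.  Note that the edge set of a full triangulation at
that segment length carries several times the lumen volume of the reference
tube-model morphometrics; the tube solver is kept for closed-form
verification (series/parallel composition to 1e-10) and for cross-checking
the direction of connectivity trends, not for absolute morphometry.  The
sheet model is the primary one throughout.

## Connectivity study and regressions

Six model sets around the default: vessel number 1–5 (symmetric, arteriole-
only, venule-only) and vessel diameter 20–60 µm in steps of 10 (same three
variants).  Each configuration runs on four replicates: two fresh pore
layouts (seeds 11 and 12 by default) and their mirrors.  Targets are
regressed against the total arteriolar lumen area A = n·π(d/2)² by OLS over
replicate-level rows; the velocity fits of the arteriole-varying sets
overlap closely, so the inversion uses one pooled velocity fit.  Symmetric
sets use the per-side (arteriolar) area as the x-axis.

Sensitivity grids on the default geometry (Newtonian): inlet velocity
0.5–3 mm/s by 0.25; outlet pressure 500–1,500 Pa by 100; density
500–1,500 kg/m³ by 100; viscosity 1–56 cP by 5.5.  In the Stokes regime the
mean speed is exactly linear in v_in with zero intercept, Δp is linear in µ
and in v_in, and both targets are invariant to the outlet pressure level
and to density; the tests assert these properties to ~1e-6.

## Structure inference

Given an observed pair (capillary velocity v, pressure drop Δp):
A_v = (v − b)/m from the pooled velocity fit; each model set's pressure fit
yields its own area A_p.  All grid configurations (n ∈ 1..5,
d ∈ {20..60}) whose lumen area lies within 10% of A_v form the candidate
list; a candidate is flagged pressure-consistent when the pressure-implied
area of its own family (number-varying sets for d = 20 candidates,
diameter-varying sets for n = 1 candidates) agrees with A_v within the same
tolerance.  The verdict is `unique` (one flagged candidate),
`two_alternatives` (two), else `none`.  The 10% tolerance is a default and
exposed in the API; the synthetic-recovery experiment perturbs solver
outputs with 3% multiplicative log-normal noise and asks whether the
generating configuration appears in the candidate list.

## Gas-exchange link

A generic membrane-limited, Hill-kinetics transit model links capillary
speed to oxygenation; it deliberately stands in for an external
gas-exchange application and its absolute outputs are not comparable to
published values.  A blood slab transits the mean arteriole-to-venule
geodesic (363 µm) at the capillary speed while oxygen crosses the barrier at
rate k·S·(P_A − P) and loads hemoglobin via a Hill curve (P50 = 26.8 mmHg,
n = 2.7, capacity 0.201 mL O₂/mL, dissolved O₂ solubility 3.1×10⁻⁵
mL/(mL·mmHg)); P_A = 100 mmHg, inflow PO₂ = 40 mmHg.  The membrane
coefficient k = 6×10⁻¹¹ mL O₂/(mmHg·min·µm²) is chosen so oxygen
equilibrates within the first few percent of transit at the default speed —
the flow-limited regime in which oxygen saturation completes early — and is
a configuration knob, not a measured constant.  The ODE (with the gradient
integral carried as a second state) is integrated adaptively to relative
tolerance 1e-8; uptake computed as Q·Δcontent and as the membrane-flux
integral agree to that tolerance.

ΔPO₂ in the diffusing-capacity quotient DLO₂ = V̇O₂/ΔPO₂ is the endpoint
mean gradient P_A − (P_in + P_out)/2.  The transit-time average ∫(P_A −
P)dt/T is reported as a diagnostic but deliberately not used in the
quotient: it is conjugate to the uptake law, so dividing V̇O₂ by it returns
the membrane conductance k·S identically at every flow, and the quotient
would carry no information about perfusion.  With the endpoint mean, DLO₂
rises monotonically with capillary speed and its per-alveolus default
(≈7.4×10⁻⁸ mL/(mmHg·min), ≈35 mL/(mmHg·min) when scaled by 4.8×10⁸
alveoli) sits in the physiological range.  The reaction half-time (first
time at which half the total content gain is reached) normalized by transit
time grows linearly with vessel number and stays within the first quarter
of transit across the whole sweep.

## Synthetic data

The generator reproduces the study conditions: two fresh seeded geometries
plus exact mirrors (four replicates); replicate scatter of the flow targets
is well under 1%.  Noisy observations are multiplicative log-normal with a
mean-one correction and a default CV of 3%, bracketing the replicate
variability; CV = 0 reproduces solver output exactly.  What the generator
does not emulate: volumetric-mesh discretization noise, wall compliance or
breathing motion, red-blood-cell particulate effects, inter-alveolar
heterogeneity.  Passing recovery tests therefore show that the inversion
logic is self-consistent under measurement-scale noise, not that it is
robust to real-lung structural variability.

## Problem sizes and numerical defaults

Default mesh edge 4 µm (~16k triangles); the full six-set sweep is
4 replicates × 30 configurations with a shared cache for the default
configuration.  Direct sparse solves throughout; unit-cell calibration at
161² cells; Picard tolerance 1e-5 with cap 100; ODE tolerance 1e-8.  The
defaults complete the entire study (sweep + sensitivity + inference +
gas-exchange link) in a few minutes on one CPU and are bit-reproducible
given the seeds.

## Known limitations

- The thin-film closure under-predicts absolute pressure drops relative to
  volumetric CFD of the same geometry (no port-transition or entrance
  losses; potential-flow pillar drag): the default-configuration Δp sits
  ~20–25% below the volumetric reference level under both rheologies, while
  trends and ratios are preserved.
- The mass-weighted mean speed is likewise a few-percent-to-15% below
  volumetric reference values, mostly through the larger mid-surface area
  of the offset sphere.
- The Δp-vs-area slope of the diameter-varying set exceeds that of the
  number-varying set only before stub losses are added (the fixed-length
  stub loss declines as 1/d²); with the default 100-µm stubs the two OLS
  slopes are within ~3% of each other, number slightly above.
- Venule-only variation shifts the mass-weighted mean speed by up to ~6%
  at five venules (sinks spread, near-venule crowding weakens); the center
  speed is essentially unaffected.
- Transient/pulsatile flow, moving walls, particulate blood, CO₂ exchange
  and multi-alveolus coupling are out of scope.
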