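# Methods

This note records the models implemented in `coralflow`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
geometry does and does not stand in for.

## Synthetic coral geometry

The generator rasterizes the recurring structural motifs of a branching
*Acropora* skeleton into a labelled voxel volume: a vertical porous cylinder
standing on the seabed, carved by a central axial channel whose centerline
bends at a configurable number of inflection points, radial corallite
cavities spiralling from the channel to the surface, hemispherical solid
bumps co-located with the cavity mouths (the surface roughness that
corallites create), an enlarged apical corallite opening the channel at the
branch tip, and an optional through-wall defect. All primitives are
rasterized by centre-of-voxel inclusion so every count is an exact integer,
and the volume is a pure function of its parameter set including the seed.

Defaults place a 28-voxel-diameter, 96-voxel-tall branch in a 64×64×128
box with voxel spacing 0.012/28 m, so the branch diameter corresponds to a
1.2 cm, ~4 cm-tall sample; 12 radial corallites of radius 2.5 voxels and a
channel of radius 4 voxels with 3 bending points reproduce the pore-network
topology at a resolution one desktop CPU can simulate in minutes. The
defect is off by default: at this grid resolution the smallest
rasterizable through-hole is comparable in cross-section to the axial
channel itself and short-circuits the channel circulation, which a
to-scale defect on a full-resolution sample does not; runs studying
defect-site flux enable it explicitly (`defect=True`).

**Labelling.** Two label schemes coexist: segmentation output
(solid = 1, pore = 2) and the canonical analysis scheme (solid = 0, inner
pore = 1, external pore = 2). `label_inner_pores` flood-fills the pore
phase from the bounding-box faces under 6-connectivity (face adjacency —
the conservative choice for fluid percolation on voxel grids, since
diagonal adjacency would let flow pass between voxels that share no face);
unreached pore voxels are inner. Because a real branch's interior *is*
connected to the outside through corallite mouths, strict reachability
would classify the whole interior as external; two mechanisms handle this:
the generator labels its own interior exactly from its known cylinder
envelope, and for imported volumes `cap_openings=True` first closes the
solid phase morphologically with a ball (default radius 4 voxels) so
mouths narrower than the ball do not leak the flood fill. `seal_openings`
in the generator produces a strictly sealed interior for testing the
labelling itself.

**Porosity.** Both conventions used for skeletal porosity are provided and
kept distinct, because they differ: `porosity` returns pore/solid ratios —
the whole-sample variant `(pores(sample) − pores(filled)) / solid(sample)`
against a filled-reference volume, and the region variant
`pores/solid` — which can exceed 1 when pores outnumber solid, while
`porosity_fraction` is the conventional pore/total fraction in [0, 1]. The
dissolution model's initial porosity `n0` uses the conventional fraction.
Block downsampling is majority vote with ties broken toward solid, so thin
walls are never artificially perforated.

## Lattice-Boltzmann flow solver

D3Q19, single relaxation time (BGK). Collision relaxes toward the
second-order low-Mach equilibrium

    f_i^eq = w_i ρ (1 + 3 e_i·u/C² + 9(e_i·u)²/2C⁴ − 3u²/2C²),

with ρ = Σ f_i, u = Σ f_i e_i / ρ, kinematic pressure p = C²ρ/3, and
C = δl/δt the characteristic lattice velocity. Viscosity follows
ν = C²δt(τ − ½)/3.

**Boundary set** (the submerged-branch configuration): velocity inlet at
x = 0 imposing an open-channel profile by equilibrium re-initialization of
the boundary layer — half-Poiseuille u(ζ) = u_max(2ζ − ζ²), ζ measured
from the bed, by default, because it is the unique profile consistent with
the no-slip bed / free-slip surface pair (a 1/7-power profile and a
uniform profile are selectable); constant-pressure outlet at x = N_x − 1
(fixed density, zero-gradient velocity); periodic transverse sides;
free-slip sea surface (specular reflection); no-slip seabed and skeleton
surfaces via half-way bounce-back, placing walls half a cell outside the
first fluid cell — local, robust on arbitrary voxel geometry, second-order
for straight walls. A constant body force (Guo forcing, with the ½F shift
in the velocity moment) is available for channel-flow validation.

**Unit conversion and stability.** Given the voxel spacing, the time step
is set from a target lattice inlet speed (default 0.04, safely below the
low-Mach contract of 0.1); τ = 3ν δt/δl² + ½ is then checked against the
BGK accuracy window [0.55, 1.2] and δt re-adjusted to pin τ at the nearest
bound if needed. Runs start from the cold equilibrium f = f^eq(ρ=1, u=0)
with a linear inlet ramp (default 400 steps) to avoid initialization
pressure shocks. The default desk-scale envelope is grids ≤ 96×96×192 and
Re ≤ 150; coarse-grid BGK at Re in the hundreds is outside it and the
configuration validator warns accordingly.

**Quasi-steady monitoring.** The domain-average kinetic energy is sampled
every `check_every` steps; the run is quasi-steady when its relative
change stays below `tol` (default 2×10⁻⁵) for several consecutive checks.
Probe points (velocity components and pressure) can be recorded alongside.
Non-convergence within `max_steps` returns the final field flagged
unconverged rather than raising.

Validation, all in the test suite and the acceptance script: exact mass
conservation in periodic boxes over 10⁴ steps (relative drift ~10⁻¹³);
shear-wave decay reproducing ν(τ) within 0.3 % on 32³; the body-forced
no-slip/free-slip channel matching the analytic half-parabola to ~2×10⁻⁵
L∞ at 64 transverse cells; streamwise flux constancy in open-boundary
boxes.

## Internal-flow statistics

Vorticity uses central differences (one-sided at domain edges) on the
velocity field, which is identically zero on solid voxels, so near-wall
gradients respect no-slip; enstrophy is E = |ω|²/2. Statistics over
regions always mask solid voxels out.

Streamlines integrate dx/ds = u/|u| (arc-length parameterization) with
fixed-step RK4, step 0.25 voxel, and trilinear velocity interpolation
between voxel centres. A path terminates on leaving the analysis region,
entering a solid voxel, dropping below a stagnation threshold (10⁻⁶ of the
field's maximum speed), or exhausting the step budget. Residence time per
streamline is Σ |Δl| / |u| over segments starting inside the region, with
the speed taken at each segment's first point (the natural discrete
reading of the time-of-flight sum). The mean t̄ is taken over streamlines
up to the 95th percentile of residence time (the "95 % confidence"
retention), trimming near-stagnant paths that would otherwise dominate the
mean; the untrimmed times are also returned. Residence histograms are
normalized to sum to 1. The average pore flux is Q = V_innerpores / t̄.

Tracer releases mirror the 120,000-particles-from-a-radius-150-cell-centre
protocol in the function defaults, but are seeded at the centroid of the
region's *pore* voxels (not the box centre, which may be solid); desk-scale
runs use a few hundred particles and proportionally smaller radii — the
statistics quoted here used 300 particles of radius 6 cells, and at that
count the streamline t̄ agrees with an independent brute-force fixed-step
Euler advection (scipy interpolation, matched termination rules) to ~1.5 %.

The upstream/downstream asymmetry report takes equal-sized slice pairs and
returns mean(upstream) − mean(downstream) of pressure, speed and enstrophy
with combined standard errors. The axial decomposition returns per-section
mean speed and mean u_z/|u| over pore voxels, excluding cells below a
speed floor (10⁻⁹ of the maximum) whose direction is numerical noise.
Standard regions for the synthetic branch (Top/Bottom × Up/Downstream
sub-volumes; TipTop/Top/Center/Bottom channel sections at quarter-height
cuts) are generated from the geometry parameters, since on synthetic
geometry the sectioning is exact and reproducible.

At Re ≈ 10.8 on the default branch the solver reproduces the expected
qualitative structure: all upstream−downstream differences positive
(upstream dominance), the vertical velocity fraction in the topmost
channel section exceeding the bottom section's, and interior monitor
speeds two to three orders of magnitude below the free stream. These
orderings held across every generator seed tried; margins vary with seed.

## Dissolution under ocean acidification

The branch is idealized as a homogeneous aragonite tube (outer radius R_O,
inner radius R_I, length H) flushed by pore water at velocity u = Q/πR_I².
Proton transport is one-dimensional advection-reaction,
∂C/∂t + u ∂C/∂x = −r(C); diffusion is neglected as a weak transport
process at these scales. The rate law r(C) = k₁(e^{k₂C} − 1) with
k₁ = 2.5×10⁻⁷ mol m⁻³ s⁻¹ and k₂ = 1.98×10⁵ m³ mol⁻¹ is the empirical
fit to Morse's aragonite dissolution measurements (R² = 0.98, validity
roughly pH > 6); the code takes the fitted constants as given and guards
the exponential against overflow. pH converts to concentration as
C = 10^(3−pH) mol m⁻³.

The method of characteristics gives the steady profile
C(x) = −ln(1 − e^{−kx/u}(1 − e^{−k₂C₀}))/k₂ with k = k₁k₂ = 0.0495 —
derived in code from the two rate constants rather than hard-coding the
sometimes-quoted rounded value 0.0496 (a 1-in-500 difference). The
implementation evaluates it in expm1/log1p form because at pH ≤ 7 the
entrance layer involves factors as small as e^{−k₂C₀} ≈ 10⁻⁸⁶.

The independent cross-check solver discretizes the steady balance with
first-order upwind advection and an implicit per-cell Newton solve of the
stiff sink (the explicit sink would demand ~10⁷ pseudo-time steps); its
fixed point is marched cell-by-cell from the inlet, and a pseudo-time
explicit-advection variant is kept for transient checks (both satisfy the
identical per-cell relation at steady state, verified in the tests). The
default grid is geometric, starting inside the entrance reaction layer
(~e^{−k₂C₀}·u/k), because the profile decays logarithmically there and a
uniform grid cannot resolve its first cell at low pH. With 10⁴ cells the
solver and the closed form agree to ~10⁻⁴ relative L∞ across
u ∈ [10⁻⁸, 10⁻⁴] m/s and inlet pH 6–9.

**Scenarios.** With acid produced outside and advected in (scenario 1),
protons are consumed nearly completely near the entrance, so the
tube-average rate is r = uC₀/H = QC₀/(HπR_I²); the implementation verifies
the complete-consumption assumption from the analytic profile
(C(H)/C(0) < 10⁻³) and otherwise falls back to the conservative difference
form u(C(0) − C(H))/H with a warning. With a maintained low-pH
microenvironment inside (scenario 2), the rate is simply r(C(pH_local))
throughout; the calcium-efflux bookkeeping of that scenario is reduced to
this constant-rate model and the efflux concentration itself is out of
scope.

**Damage projection.** A constant average rate erodes the inner radius as
R_I(t) = R_I(0)e^{rMt/2ρ_s} (ρ_s = 2700 kg/m³, M = 0.1 kg/mol), with the
linearized first-order form available — the exponent is of order 10⁻² even
per century, so the two differ by ~5×10⁻⁵ relative. The porosity change
ratio N = (R_I²/R_O²)(rMt/ρ_s + (rMt/2ρ_s)²)/n₀ × 100 % is algebraically
identical to the skeleton-volume-difference route evaluated with the
linearized radius (asserted to machine precision in the tests). Flexural
rigidity scales as EI ∝ A², and the measured allometry between planar area
and CT volume of branching-coral skeletons, log V = 1.4728 log A − 1.5275
(taken as given), converts this to remaining skeleton volume:
G = (V₀^e − V_t^e)/V₀^e × 100 % with e = 2/1.4728 = 1.358. V_t is the
remaining *solid* tube volume π(R_O² − R_I(t)²)H, so dissolution gives
positive G. Years convert to seconds with the Julian year (3.1557×10⁷ s).
The 2023 baseline ambient pH is a configuration parameter (default 8.10).

## Pipeline

One global seed fans out per-stage sub-seeds through SHA-256 so a single
integer reproduces the whole chain; every stage writes standard formats
(TIFF+JSON geometry, HDF5 fields, CSV tables, optional legacy-ASCII VTK)
and a manifest records the configuration hash and per-artifact checksums.
Configuration validation separates blocking errors (unknown stages,
missing files, τ ≤ ½) from warnings (Re above the desk-scale envelope,
lattice Mach > 0.1).

## Problem sizes and limitations

The defaults are chosen so the full chain runs on one desktop CPU: the
quasi-steady coral run uses the 64×64×128 grid at Re ≈ 10.8 (a few
minutes with the numba kernels), physics validations use 32³ (shear wave),
64 transverse cells (channel) and 20³ (conservation), the transport
cross-check uses 10⁴ cells, and Lagrangian statistics use 300 tracers.
The synthetic branch reproduces pore-network *topology* and flow-regime
structure, not the multiscale surface texture, sub-voxel microporosity or
specimen-specific geometry of a micro-CT scan, so desk-scale results
support qualitative orderings (upstream dominance, axial-flow dominance
near the tip, interior/exterior speed separation) rather than the absolute
magnitudes a full-resolution sample would give. Turbulent regimes
(Re ≳ 350 on coarse grids) are outside the BGK stability envelope here;
no turbulence model, free-surface tracking, moving boundaries or
carbonate-system speciation (DIC, Ω_aragonite) is included, and
dissolution does not feed back into the flow geometry over time.
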