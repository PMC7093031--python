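# Methods

`hemoflow` is a desk-scale, cell-resolved model of blood flow with stiffened
red blood cells (RBCs): a D3Q19 lattice-Boltzmann plasma coupled by the
immersed-boundary method to coarse-grained membrane models of healthy RBCs,
oxidatively stiffened RBCs, and platelets, together with the analysis
pipeline for the quantities such a study reports — elongation index,
pair-collision displacement, radial diffusivity, hematocrit profiles,
cell-free layer (CFL) width, platelet margination, and the Beer–Lambert
depth correction of confocal Z-stacks.  "Desk scale" means every protocol
runs on one CPU core in seconds to minutes; geometries and resolutions are
reduced accordingly, and the targets are the qualitative orderings that
survive this reduction, not full-scale absolute profiles.

## Membrane model

Each cell is a closed triangulated surface (icosphere subdivision mapped to
the target shape; 162 vertices in dynamic runs, 642 for geometry work).  The
RBC resting shape is the classic quartic biconcave profile

    z(x) = ±(D/4) α √(1−x²) (C0 + C1 x² + C2 x⁴),   x = 2r/D,

with C = (0.207161, 2.002558, −1.122762), D = 8 µm, and the thickness scale
α chosen once so the enclosed volume is 90 µm³ (area ≈ 134 µm², dimple
thickness ≈ 0.7 µm, rim ≈ 2.2 µm).  Platelets are oblate ellipsoids of
2.4 × 2.4 × 1.0 µm, radially rescaled so the mesh volume equals the analytic
ellipsoid volume at any subdivision level.

The membrane force is the superposition of four conservative terms, each the
gradient of a rotation- and translation-invariant energy (hence exactly
force- and torque-free per cell):

* **link** (spectrin stretching), per edge with strain dL = (L−L0)/L0:
  magnitude κ_l·dL/p·[1 + 1/(τ_l² − dL²)], persistence length p = 7.5 nm,
  expansion ratio τ_l = 3 (the law diverges as the network approaches its
  persistence length).
* **bend**, per interior edge on the dihedral-angle deviation from the
  resting shape, with the same pole structure and the pole at τ_b = π
  (complete fold).
* **area**, per triangle on the relative area deviation, pole at τ_a = 1
  (triangle collapse / doubling), plus a whole-cell penalty on the total
  area deviation that models the lipid bilayer's areal incompressibility
  (a cell-level property, distinct from the local spectrin elasticity).
* **volume**, a global quasi-incompressibility penalty on the relative
  enclosed-volume deviation, acting along the discrete volume gradient.

Strains are guarded at 0.98 of each pole: single-cell protocols raise a
stability error naming the element (the stiff models genuinely cannot
sustain shear stresses of roughly 2 Pa, and the error surfaces that);
bulk runs may clamp-and-count instead.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| κ_link | 15 / 90 / 600 / 25 | kBT | healthy / 0.5 mM / 0.75 mM TBHP / platelet stretch stiffness |
| Λ | 1 / 6 / 1 / 1 | — | interior/exterior viscosity ratio of the same four models |
| p | 7.5 | nm | spectrin persistence length |
| τ_l | 3 | — | link expansion ratio (pole) |
| κ_bend | 80 | kBT | dihedral stiffness |
| κ_area | 635.568 | kBT | local area stiffness (calibrated, see below) |
| κ_area_global | 1.2e7 | kBT | whole-cell bilayer area penalty |
| κ_volume | 1e7 | kBT | whole-cell volume penalty |

kBT is evaluated at T = 300 K (4.14195e−21 J); the sources quoting these
coefficients give them in kBT without a temperature, and room temperature is
the conventional reading.  The two global penalties are numerical
constraint stiffnesses, not fitted elastic moduli: they are set so that
volume drift stays below 1% and total-area drift below 2% in the most
violent single-cell protocol (strain 10 at 1.1 Pa), while remaining well
inside the explicit-coupling stability limit.

### Patch Young's modulus and the area calibration

The surface Young's modulus of a membrane model is measured on a single
regular hexagonal patch (one centre vertex, six boundary vertices, six
equilateral triangles) at the mean edge length of the default RBC mesh
(0.509 µm).  A uniaxial strain is prescribed on the boundary x-coordinates;
every other in-plane coordinate relaxes quasi-statically (free lateral
contraction), and the modulus is the Richardson-extrapolated small-strain
slope of tension versus strain at ±0.5% and ±1%.  Elements enter with
periodic-tiling weights (perimeter edges half, triangles whole), so the
measured slope is that of the extended membrane lattice rather than of an
isolated seven-vertex island; with links only, the numerical result matches
the continuum triangular-spring-network value E = 2k/√3 to six digits.
The whole-cell area and volume penalties are cell-closure constraints and
do not enter the patch (a flat open patch has no enclosed volume and its
total-area change is the integral of the local term it already contains).

κ_area is the one calibrated constant: it is solved (once, and shipped as
the default) so the healthy model's patch test returns the validated healthy
modulus of 27.82 µN/m.  With that single healthy calibration the 600 kBT
model measures 854.6 µN/m, within ~6% of its 808 µN/m reference.  The
90 kBT model measures 140.8 µN/m against a 244.04 µN/m reference, and this
gap is structural, not a tuning failure: in any linear-elastic patch
protocol where only κ_link differs between models, the modulus is an affine
function of κ_link, and no affine function passes through all three
reference points (the secant slopes between the reference pairs differ by a
factor of two).  A quasi-static modulus also cannot depend on that model's
viscosity ratio Λ = 6, which is its only other distinguishing parameter.
The 140.8 µN/m value is therefore reported as measured.

## Fluid solver and coupling

Single-relaxation (BGK) D3Q19 lattice with Guo forcing; halfway bounce-back
walls implemented through the streaming neighbour table, with a momentum
correction for moving walls (plane Couette is then exact at steady state).
The time step follows from the relaxation time and the plasma viscosity,
ν = (τ_LB − ½)/3 · dx²/dt with ν = 1.1e−6 m²/s and ρ = 1025 kg/m³; at the
reference resolution dx = 0.5 µm, τ_LB = 1.1 this gives dt = 45.5 ns (a
printed 0.1 µs time step for the same triple is not consistent with this
relation; the solver derives dt and logs it).  Tubes are staircase
approximations along the axis; the wall flag threshold sits at R + 0.05 dx,
which centres the effective (mid-link) boundary on R — validated against
the Poiseuille closed form to 1.2% at R = 10 µm, dx = 0.5 µm.  Stability
guards: positive density, lattice Mach bound |u| < 0.5, wall speed < 0.1.

Viscosity contrast assigns interior fluid nodes τ = ½ + Λ(τ_LB − ½) by
even-odd ray parity against the closed surface (recomputed on demand; the
0.75 mM model used in all bulk protocols has Λ = 1, so the contrast is
exercised by the API and its tests, not the bulk runs).  Note Λ = 6 at
τ_LB = 1.1 puts interior nodes at τ = 4.1, outside the (0.5, 2] bound that
is enforced for plasma nodes; interior nodes are exempt by design.

Membrane–fluid coupling uses the 4-point smoothed-delta kernel (2-point hat
available).  Kernel weights are computed once per step and shared between
force spreading and velocity interpolation; spreading conserves total force
exactly (partition of unity) and linear velocity fields interpolate to
round-off.  Vertices advect by forward Euler with the interpolated
velocity.  Vertex coordinates stay unwrapped along periodic directions
(membrane geometry is always single-image); cells are re-folded by whole
periods every 200 steps with the accumulated shift kept, so trajectories
are continuous.

Because dx in the bulk protocols (1.4 µm) cannot resolve lubrication in
sub-grid gaps, cells interact through an explicit short-range contact force:
a linear repulsion between vertices of different cells within one lattice
spacing (4 pN at full overlap), plus a wall margin force over the outermost
0.6 µm.  This is a numerical contact model standing in for the unresolved
lubrication layer; it is pairwise equal-and-opposite, so it injects no net
momentum.

## Protocols and problem sizes

* **Elongation index.**  One cell in a plane-Couette box (20×16×14 µm,
  dx = 1 µm, τ_LB = 1.4), equilibrated to strain γt = 5, then EI sampled at
  10 points over two further strain units (the desk-scale counterpart of the
  full-scale 35 ms window).  EI is computed from the second moments of the
  flow-plane projection of the vertices, EI = (A−B)/(A+B).  At 1.1 Pa the
  healthy model reaches EI ≈ 0.46 while the 0.75 mM model stays below 0.05.
* **Pair collisions.**  Two cells in a 48×16×12 µm shear box (dx = 1.4 µm,
  τ_LB = 2.0) at 500 1/s, 16 µm apart streamwise, each offset 2 µm from the
  mid-plane, disc faces parallel to the flow–vorticity plane; ten replicate
  configurations (five in-plane orientations of the incoming cell × a
  position swap); |ΔY|(γt) tracked to strain 10, the final displacement
  averaged over the trailing strain unit to suppress tumbling-phase
  aliasing.  On the offset convention: with a *relative* offset of 2 µm the
  desk-scale pair robustly drafts into a lane-swapping trajectory instead of
  passing (verified at dx = 1.4 and 1.0 µm), so the per-cell reading, which
  reproduces the passing phenomenology of such collision studies, is used.
  The box length ensures the periodic images do not collide a second time
  within strain 10.
* **Tube flow.**  Periodic tube of R = 9 µm, L = 20 µm (dx = 1.4 µm,
  τ_LB = 2.0), 30% tank hematocrit (17 RBCs) plus 6 platelets (enriched
  above the physiological number ratio for counting statistics), driven by
  a body force at a 1000 1/s wall shear rate for 12 ms (γt ≈ 12);
  observables from the trailing half.  Initial placement: random sequential
  insertion of bounding ellipsoids with rejection, then a soft push-apart
  relaxation — deterministic per seed, non-overlapping, inside the wall
  margin; hematocrit within 1% of target by construction.  Both the static
  tube hematocrit and the flux-weighted discharge hematocrit are reported;
  at this confinement (cell diameter 8 µm in an 18 µm tube) the
  Fåhraeus separation between them is marginal.

## Analysis definitions

* **Radial diffusivity**: non-overlapping windows (0.5 ms) of the scalar
  radial coordinate; a window contributes Δr²/(2Δt) to the bin of its
  *starting* radius; seven equal bins tiling [0, R]; bins never visited are
  flagged missing (NaN), not zero.
* **CFL width**: per snapshot and azimuthal sector (12 sectors), the gap
  between the wall and the outermost membrane vertex in the sector (the
  wall radius if empty), averaged over sectors and snapshots, per species.
* **Volume-fraction profiles**: even–odd voxel membership at half the
  lattice spacing, per species; the platelet profile is additionally
  reported as C_plt, the local fraction over its bin-volume-weighted vessel
  mean (weighted mean of C_plt is 1 by construction).
* **Margination index**: platelet concentration within a wall band (4 µm in
  the simulated metric, 5 µm in the in-vitro-style metric; both supported)
  divided by the same quantity in a reference run (the healthy-only case,
  same seed).
* **Confocal correction**: base-10 absorbance (plate-reader convention);
  transmittance T = 10^(−A(λ)·path/L_sample) with L_sample = 3.108 mm,
  A(λ) linearly interpolated, the optical path measured from the
  objective-side wall; corrected = raw / T, emission-path only (a separate
  excitation-path correction is not modelled); uncertainties from intensity
  and absorbance standard deviations combine in quadrature; depths with
  T below 1e−6 are flagged unreliable instead of divided.

## Synthetic data

The generators provide ground-truth-known inputs for every analysis stage:
radial Brownian tracks with prescribed (optionally position-dependent)
diffusivity and reflecting boundaries, generated directly as a 1-D radial
walk so the scalar-r MSD estimator is free of the geometric bias a 2-D walk
would introduce; radial position ensembles with a prescribed CFL width and a
near-wall platelet excess added on top of a uniform base density (so the
margination oracle equals the prescribed excess exactly); and Z-stacks
attenuated by the Beer–Lambert law with optional Gaussian noise.  They
emulate none of the hydrodynamic correlations between real trajectories, so
passing estimator tests demonstrates estimator correctness, not simulator
fidelity.

## What the desk-scale protocols do and do not reproduce

Measured at the shipped defaults (ten replicate configurations per collision
pair; five seeds × three stiffness fractions for the tube study):

* Homogeneous collisions behave as full-scale studies report: the stiff–stiff
  pair shows the larger maximum displacement during the collision
  (0.63 µm vs 0.41 µm for healthy–healthy) and the smaller final
  displacement (0.26 µm vs 0.35 µm), i.e. rigid pairs approach the
  time-reversible Stokes limit while deformable pairs lose displacement to
  membrane deformation.
* The heterogeneous (healthy–stiff) collision reproduces the larger *maximum*
  excursion of the stiff cell (0.64 µm vs 0.45 µm) but **not** the larger
  *final* displacement: the stiff cell relaxes nearly reversibly to
  ~0.14 µm while the compliant cell's deformation-induced lateral migration
  leaves it at ~0.26 µm.  At this resolution the single-cell migration of
  the deformable cell is of the same order as the collision displacement
  itself and dominates the tail of the trajectory.
* In the reduced tube the CFL ordering emerges (healthy-only wider than
  stiff-only in every seed), but the near-wall platelet index of the 50/50
  mixture does not drop below the healthy-only reference within the 10 ms
  accessible at desk scale — platelet redistribution physically develops
  over seconds — and the radial-diffusivity profile is flat to decreasing
  rather than increasing toward the wall, because radial cell motion is
  strongly suppressed by confinement at 30% hematocrit in an 18 µm tube.

## Known limitations

* The desk-scale resolution (5–6 lattice nodes per cell diameter in bulk
  runs, τ_LB at the upper bound) trades accuracy for step size; see above
  for which full-scale orderings survive it.
* The reduced tube (R = 8.5 µm) confines 8 µm cells strongly; CFL widths are
  fractions of a micrometre and the tube-versus-discharge hematocrit
  separation nearly vanishes.  Orderings across stiffness fractions, not
  absolute values, are the meaningful output.
* No thermal membrane fluctuations, adhesion, aggregation, or remeshing;
  no non-Newtonian closure (all rheology emerges from resolved cells).
* The contact force and wall margin are numerical regularisations; results
  within one contact range of a surface are not quantitative.
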