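# Methods

`orbitmech` simulates the soft-tissue outcome of orbital decompression
surgery for thyroid eye disease (TED): how much intraorbital tissue a
given intervention releases into the extraorbital space, and how the
minimally invasive lateral valgization (LAVA) of the lateral orbital wall
compares to conventional wall resection.  Because patient CT data of this
kind are not publicly available, the package is built around a synthetic
orbital phantom with exact analytic ground truth; every downstream stage
is verified against closed forms or independent oracles.

## The mechanical model

Soft tissue is treated as an isotropic, homogeneous, piecewise linear
elastic (Hookean) material.  The displacement field u under applied
forces f solves the Lamé–Navier equations of linear elastostatics,

    Δu + (1 − 2ν)⁻¹ grad div u = −2(1 + ν) E⁻¹ f,

with Young's modulus E and Poisson ratio ν per tissue.  The
discretization uses linear (P1) tetrahedra, a consistent load vector for
surface tractions, and exact elimination of Dirichlet constraints with a
sparse direct factorization (deterministic ordering, relative residual
checked).  "Piecewise linear" is realized incrementally: loads and
prescribed displacements are applied in equal increments (default
n_steps = 10) with node coordinates updated and the stiffness reassembled
between increments.  An update that inverts an element aborts the solve
with the step and element reported.

ν is capped at 0.49 by default to keep P1 elements away from volumetric
locking; the cap is applied per solve and logged.  Units are mm and kPa
throughout (forces in mN).

Verification battery (all in the test suite and acceptance script):

- patch test: affine Dirichlet data reproduced to machine precision;
- pressurized thick-walled sphere (a = 10 mm, b = 20 mm) against the Lamé
  closed form u(r) = p a³/(E(b³−a³)) [(1−2ν) r + (1+ν) b³/2r²], with
  monotone error decay over three refinements (13.9% → 4.5% → 1.9%
  volume-weighted relative L2 on the levels shipped);
- exactly six near-zero eigenvalues of the unconstrained operator.

The sphere benchmark runs on a cube-sphere structured shell mesh (each
hexahedral cell split into 24 tets through its cell and face centroids,
conforming by construction; boundary nodes placed exactly on the
spheres).  Rigid-body motion is removed by six point constraints on
on-axis nodes, consistent with the purely radial exact solution.

## The phantom

The bony orbit is a truncated cone (apex posterior, rim anterior; default
depth 45 mm, rim radius 18 mm, apex radius 5 mm), voxelized at 1 mm
(default grid 56×64×56).  A spherical bulbus (r = 11 mm) sits near the
rim; four rectus-like muscle tubes (r = 2.5 mm) run along the cavity at a
radial offset following the taper, ending behind the bulbus so their
volume keeps the exact Cavalieri closed form; fat fills the rest.  Bone
is a 2 mm shell with apex cap and an anterior lid (standing in for the
orbital rim/septum) so the cavity is topologically closed; a temporalis
body occupies a 6 mm shell sector outside the lateral wall.  Wall sectors
(lateral/floor/medial/roof) partition the cone's 360°; the lateral sector
angle (102.1°) is calibrated so its slant area is ≈ 9.6 cm², the scale of
a deep lateral wall fragment.  Axes: x lateral, y anterior, z superior;
world = origin + (index + 0.5)·voxel.

What the phantom does **not** emulate: real orbital anatomy is neither
conical nor axisymmetric, muscles insert on the globe, the bone thickness
varies, and segmentations carry noise and partial-volume effects.
Passing tests therefore demonstrate correctness of the mechanics and the
bookkeeping on a geometry where ground truth is exact — not clinical
validity on any patient.

## Meshing

Deformable tissues (fat, muscle, bulbus) are meshed by resampling the
labelmap to the target edge length (nearest neighbour at cell centers)
and splitting each deformable cell into 6 Kuhn tetrahedra — fully
deterministic, conforming, uniform 45° minimum dihedral angle.  Bone is
never meshed; it enters only through boundary facet tags (wall sector by
centroid angle, APEX_FIXED within a band of the apex, ANTERIOR_FREE at
the rim plane).  The staircase boundary this leaves is compensated where
it matters rather than removed: wall areas are facet areas projected onto
the analytic cone surface, and released volume is measured relative to
the undeformed mesh occupancy (below).  An optional snapping mode
projects boundary nodes radially onto the cavity surface with a local
scale-back wherever an element would drop below a volume floor; it is off
by default because the near-boundary slivers it creates are exactly where
the valgization contact band applies large displacements.

Iso-surfaces for export/inspection use marching cubes on the binary mask
followed by a few shrink-free Taubin smoothing passes (binary-mask
contours otherwise inherit the staircase and overestimate curved areas;
10 iterations reproduce a sphere's area to ~2% and a cube's volume to
~1.5%).

## Surgical scenarios

A plan selects contiguous wall fragments (full sector or an angular/axial
sub-window) and is compiled into per-step boundary conditions:

**Resection** removes the fragments: window facets become Neumann with
traction p·n̂ (intraorbital pressure pushing outward), the remaining wall
and apex are fixed, the anterior aperture is traction-free.  Facets whose
outward probe (cast along the analytic wall normal, several depths) lands
in the temporalis are kept fixed instead: the herniating muscle blocks
outflow there.  This is the mechanism that makes an isolated lateral
resection release little tissue while a floor resection releases much
more.

**Valgization (LAVA)** keeps the lateral fragment and moves it rigidly:
rotation by the valgization angle about a hinge on the fragment's
anterior edge (principal axis of the anterior edge vertices; rotation
sense chosen outward) composed with a shift along the mean outward
normal; defaults 2.5 mm and 30°.  Soft-tissue nodes within the contact
tolerance (1 mm) of the fragment follow this motion as Dirichlet data,
applied along the rotation arc in increments.  Step (ii) pressurizes the
gap opened along the osteotomy cut on the updated geometry, while tissue
still in full contact with the displaced fragment stays held.  Because
the fragment carries the temporalis outward, the valgized window is never
blocked.

Bone–tissue coupling at the cut is a genuinely open modeling choice; the
package makes it explicit with two plan parameters: a **release ring**
(default 3 mm, at least one element layer) around the fragment rim where
tissue is bonded to neither the fragment nor the wall, and a smoothstep
**blend** (default 8 mm) over which the prescribed motion ramps from zero
to the full rigid transform.  Without them the kinematic discontinuity at
the cut inverts elements at any practical resolution — prescribing a
~18 mm displacement one element away from fixed bone is not meshable —
and with them the prescribed field is the natural kinematics of tissue
freed along the cut.  Both are configurable; setting them to zero
reproduces the raw rigid-contact contract (used by the unit tests of the
compiler).

Node-level conflicts are resolved by Dirichlet precedence: a node shared
between a pressurized window facet and a fixed wall facet stays fixed,
and its traction contribution is dropped by the constrained solve.
Contradictory Dirichlet prescriptions are rejected by name.

## Outcome metrics

**Released volume** is the volume of deformed tissue outside the original
bony cavity.  Deformed and undeformed tetrahedra are rasterized on a
shared lattice (default 0.75 mm for reports, 0.5 mm for oracle tests) and
the measure counts points that are outside the analytic cavity, covered
by the deformed tissue, and *not* covered by the undeformed tissue.
Referencing the undeformed occupancy makes the zero-displacement baseline
exactly zero on any mesh, so the staircase boundary does not bias the
result.  Verified against the closed form A·t for a rigidly translated
slab (exact at 0.5 mm) and against an independent brute-force membership
count (<1%); self-converges under lattice refinement (<1% between 1.0 and
0.5 mm on the LAVA field).  A boundary-flux mode (Σ max(ū·n̂,0)·A over
the original boundary) provides a fast first-order cross-check and is the
observable used inside the inverse loop.

**Proptosis change** is the recession of the anterior-most bulbus node
along +y (positive = eyeball recedes).  Reports carry affected area
(cm²), released volume (cm³), their ratio, and a per-tissue breakdown;
`compare_scenarios` adds pairwise ratio-of-ratios.

## Material parameters and the study conditions

The defaults are fixed once: fat is the reference tissue (E_fat = 1 kPa),
E_muscle/E_fat = 4, E_bulbus/E_fat = 30, ν = 0.45 for all soft tissues,
intraorbital pressure p = 0.2 kPa, hence p/E_fat = 0.2.  Reported soft
tissue moduli span roughly 1–30 kPa with muscle a few times stiffer than
fat and the globe much stiffer; in the traction-driven linear regime only
the ratios matter, and p/E_fat = 0.2 produces outflow displacements of a
few millimetres, the scale seen in decompression outcomes.  With these
conditions the shipped comparison on the default phantom gives LAVA
2.62 cm³ released through 8.85 cm² (0.296 cm per unit area) versus
two-wall resection 0.62 cm³ through 17.24 cm² (0.036 cm) — the
valgization scenario releases several times more volume per unit wall
area, reproducing the qualitative clinical finding that motivates LAVA.
The absolute volumes of any real case depend on patient anatomy and
individual tissue parameters and are outside what a schematic phantom can
state.

## Inverse estimation

Traction-driven linear elasticity fixes only ratios, so the identifiable
coordinates are (p/E_fat, E_muscle/E_fat, ν); requesting a joint fit of
absolute E_fat and pressure raises an explicit identifiability error
rather than silently returning one point of the ridge.  The objective is
a weighted sum of squared normalized discrepancies in released volume
(flux mode) and sparse surface-displacement samples; it is zero iff the
simulation reproduces the observations.  The optimizer is Nelder–Mead in
log coordinates for the ratios with bound projection and seeded random
restarts (default seed 17, 3 starts); accepted-iterate objectives are
non-increasing by construction, and an init that already fits returns
immediately.  On the default phantom (4 mm model, single-step resection
forward model, 30 samples + volume) noiseless recovery is exact to
optimizer tolerance, and with 5% multiplicative observation noise the
median p/E error over 10 replicates is ~1–2%.

## Numerical choices and problem sizes

- Direct solver: SuperLU on the reduced SPD system; assembly and
  reduction are fully vectorized and deterministic.
- Default pipeline: 1 mm phantom, 2 mm mesh (~3.3k nodes), 10 increments
  per surgical step, 0.75 mm outcome lattice — chosen so the full
  LAVA-vs-two-wall comparison completes in well under a minute while the
  released-volume measure is converged to ~1%.
- Sphere benchmark levels (2,2)/(4,3)/(6,5) cube-sphere subdivisions:
  the finest reaches the asymptotic regime at ~5.8k nodes.
- All randomness (inverse restarts, observation noise) flows through
  explicit seeds; identical configurations produce byte-identical
  reports.

## Known limitations

- Linear kinematics per increment: large rotations are followed
  incrementally but no objective (hyperelastic) constitutive law is used;
  step (ii) tractions follow the deformed facet normals, step (i) is
  displacement-driven.
- No contact mechanics: temporalis blocking is binary (fully blocked
  window facets), not a unilateral constraint; tissue self-contact is not
  detected.
- The phantom's schematic geometry means absolute outcome numbers are
  illustrative; only verified quantities (oracle agreements, scaling
  laws, scenario orderings) carry over.
- The anterior aperture is traction-free; proptosis reduction therefore
  arises from tissue leaving through the windows, not from a modeled
  retro-bulbar pressure drop.
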