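# Methods

This note documents the models, algorithms and numerical choices behind
`brainshift_xfem`: a serial, incremental update of intraoperative brain MR
images across surgery, driven by a linear-elastic tetrahedral biomechanical
model with XFEM Heaviside/hole enrichment for resection cavities.

## Problem setting and incremental strategy

A craniotomy case produces a time-ordered series of intraoperative images
I_1 … I_n (here five): I_1 before the skull is opened, I_2 after opening
(brain shift), I_3 … I_5 after successive resections. The goal is to warp
each image into registration with its successor — and, cumulatively, to
carry I_1 forward — so that the surgeon's reference imagery remains valid
as the brain deforms.

For each consecutive pair (I_k, I_{k+1}) the pipeline (i) tracks surface
landmarks between the two images, (ii) applies the resulting displacement
increments as Dirichlet boundary conditions to the biomechanical model,
(iii) solves for the volume displacement increment, and (iv) warps the
image. Landmarks are always tracked between the next-to-last and last
acquired images, never first-to-last: intraoperative motion can reverse
direction, and each increment uses the freshest geometry.

Because the constitutive model is linear (small strains, small
displacements), every increment is solved **on the initial mesh
configuration** and the increments superpose:

    eps^{n+1} = sum_k  Delta eps_k^{k+1},    sigma = C eps.

The mesh built from I_1 is therefore never rebuilt or deformed in place;
the "current configuration" is always initial coordinates plus the
accumulated displacement field. This keeps element quality constant across
arbitrarily many deformation steps — the entire point of handling
resection discontinuities by enrichment rather than remeshing.

## Biomechanical model

**Geometry.** The whole-brain region (healthy brain ∪ tumor) of the first
image's segmentation is meshed by a structured lattice split: the voxel
lattice is coarsened toward a target edge length (default 5 mm), each
retained hexahedral cell is cut into 6 Kuhn tetrahedra sharing the main
diagonal. The split is translation-invariant, hence conforming across
cells and bitwise deterministic. A cell is kept when at least 4 of its 8
corner voxels are brain — a volume-neutral rule (an all-corners rule loses
tens of percent of a sphere's volume at coarse cells; the majority rule
keeps the mesh volume within a few percent of the analytic volume, and
within one boundary-voxel layer of the voxel-count volume at native
resolution). Each tetrahedron is tagged healthy/tumor by its centroid
voxel, so the internal tumor interface coincides with element facets and
interface nodes are shared — the conformity the downstream boundary
conditions rely on.

**Constitutive law.** Isotropic linear elasticity, E = 3000 Pa,
ν = 0.45. Only displacement (no force) boundary conditions are applied, so
the solution is invariant to E — asserted in the tests to 1e-10 — and the
initial stress state, which is unknown intraoperatively, is set to zero
for every solve. Elements are constant-strain tetrahedra with linear nodal
shape functions φ_i on supports ω_i (the union of elements incident to
node i):

    u^FEM(x) = sum_{i in I} phi_i(x) u_i.

Dirichlet data are imposed by symmetric row/column elimination (the free
block stays symmetric positive-definite; penalty methods were rejected for
conditioning). The free block is factorized with sparse LU; a conjugate
gradient fallback at 1e-10 relative tolerance exists for the rare
factorization failure.

## XFEM resection modeling

A resection removes tissue: the removed part must stop influencing the
remaining part. Instead of remeshing, the displacement field is enriched:

    u^XFEM(x) = sum_{i in I} phi_i(x) u_i  +  sum_{j in J} phi_j(x) g(x) a_j,

where J is the set of nodes whose support is fully intersected by the
discontinuity and each j ∈ J carries three extra DOFs a_j. An unaffected
node keeps 3 DOFs; a fully-cut node has 6. The discontinuous function g is
either the Heaviside function H(x) = ±1 — sign of (x − x*) · e_n, with x*
the closest point on the crack and e_n its outward normal — or the hole
function V(x) ∈ {1, 0} that zeroes the removed (negative) side.

Orientation convention: crack normals point **away from the removed
side**, so the retained tissue is the positive side of both functions.

**Hole vs Heaviside.** For pure resection the hole function is sufficient
and gives identical results on the retained side; Heaviside is kept for
both-sides-constrained problems (and would be needed for retraction).
The pipeline default is `hole`, implemented as void integration: elements
and subcells on the negative side contribute zero stiffness, and DOFs left
without stiffness are pinned to zero. This choice also sidesteps a
degeneracy of Heaviside enrichment on a closed cavity: the enclosed
removed material would float (unconstrained rigid modes), since boundary
conditions are applied to the healthy boundary only.

**Geometry queries.** The crack is any oriented triangulated surface. Side
classification uses exact point-to-triangle projection (k-nearest
candidate triangles from a k-d tree over centroids) and the angle-weighted
pseudonormal of the closest feature (face/edge/vertex), which gives a
correct sign for watertight surfaces; an open crack is effectively
extended along its closest feature, i.e. the front is snapped outward —
consistent with treating front elements as not-cut (no branch-tip
enrichment; the modeled resections are through-cuts or closed cavities).

**Enrichment rule and conditioning.** Node j enters J when both sides of
the crack hold positive volume within ω_j; enriched DOFs whose smaller
side is below 1e-4 of the support volume are eliminated (standard XFEM
ill-conditioning guard). Points within 1e-6 of a characteristic crack
edge of the surface are treated as on-crack and perturbed.

**Cut-element quadrature.** A cut tetrahedron is subdivided by the zero
level of the linearly interpolated signed side values of its corners
(marching-tetrahedron cases: 1-vs-3 gives an apex tet plus a 3-tet prism,
2-vs-2 gives two 3-tet wedges sharing the cut-quad diagonal). All subcell
faces are planar, so the decomposition is exact and conserves the parent
volume to machine precision (asserted at 1e-12 over 1000 random cuts).
Shape-function gradients are those of the parent element and g is
piecewise constant, so one-point quadrature per subcell is exact.

**Boundary conditions at enriched nodes.** Enrichment is unshifted
(exactly the expression above), so a prescribed nodal value is meaningful
only where the node is not enriched. When a constrained node is
nevertheless enriched, its standard DOFs are prescribed and its enriched
DOFs pinned to zero. A useful consequence: when displacements are
prescribed on the entire healthy-region boundary and the discontinuity
stays clear of healthy elements, the healthy-region equations of FEM
(ignoring the crack) and XFEM coincide **exactly**, which realizes the
complete-resection equivalence at the discrete level (verified to solver
tolerance in the acceptance suite). With tumor remnants the two differ in
the remnant; on the patient scale that difference is known to be
sub-voxel, and the package reports it rather than asserting it.

## Surface-landmark tracking

Landmarks are region boundary *surfaces*: the whole-brain boundary and the
internal tumor boundary (tracked via the closed healthy-brain boundary).
Before any resection both are used; from the first resection on, only the
healthy-brain boundary is tracked — part of the whole-brain boundary no
longer corresponds to the same physical entity.

For an interval (I_k, I_{k+1}):

1. The model boundary, posed at its accumulated configuration, is relaxed
   onto I_k's region boundary (active surface against I_k's distance map).
   This anchors material correspondence and removes lattice jaggedness
   from the measured displacement.
2. The relaxed surface is optionally pre-aligned **rigidly** along the
   internal tumor boundary with iterative closest point (centroid-difference
   initialization, closed-form rigid fits, RMS-non-increasing iterations):
   distance-map forces cannot represent locally rigid tangential motion.
3. The surface then evolves onto I_{k+1}'s boundary; the per-vertex
   displacement between steps 1 and 3 is the landmark increment.

**Active surface.** Vertices follow
x ← x + step · (−D(x) ∇D(x) + α · umbrella(x)) with D the unsigned
Euclidean distance map of the target boundary (anisotropy-aware exact
distance transform) sampled trilinearly. The external force is the
gradient of D²/2: the plain −∇D descent oscillates across the kink of an
unsigned distance with amplitude ~step, while the damped form converges
smoothly and sub-voxel. Defaults: step 0.3 (dimensionless), α 0.2, at most
200 iterations, stop when mean motion < 1e-3 mm. These are package
choices; no published values exist for them.

**Smoothing and transfer.** Displacements are averaged with each vertex's
N = 8 nearest vertices (five to ten are appropriate; inverse-distance
weights 1/(d + d̄/2) so a constant field is a fixed point), then
interpolated barycentrically at each model boundary node's closest point
on the tracked surface to form the Dirichlet increment. Nodes farther
than 1.5 target edges from the tracked surface are an error.

## Image warping and validation

The solved increment is rasterized to a dense voxel field (barycentric
interpolation inside the mesh posed at the interval's configuration) and
applied by **forward splatting**: every source voxel is displaced as a
rigid box and deposited with per-axis overlap weights; each output voxel
is the overlap-weighted mean of its contributions; uncovered voxels inside
the target brain copy their nearest covered neighbor (logged). The
pipeline composes warp → whole-brain mask → resection background (value
0), with masks taken from the target image of the pair.

Similarity between two images is measured on Canny edges extracted
slice-wise from the whole-brain-masked image (σ = 1 voxel; hysteresis
thresholds at the 70th/90th percentile of the gradient magnitude over the
active pixels — thresholds are taken over the masked image's own gradient
distribution so the region boundary is itself an edge), converted to world
mm, under the modified Hausdorff distance

    H(A, B) = max(h(A, B), h(B, A)),   h(A, B) = (1/N_a) sum_a min_b |a − b|,

whose averaging suppresses outlier edge voxels. Two protocols are
reported, each on the whole-brain mask and on a tumor-neighborhood mask
(tumor of I_1 dilated by 25 mm): pairwise H(I_k, I_{k+1}) vs
H(I_k^w, I_{k+1}), and cumulative H(I_1, I_{k+1}) vs H(I_{1,k}^w, I_{k+1}),
the latter exposing error amplification across the series (reported, not
asserted — amplification is expected).

## Synthetic phantom

No patient data ships with the package; a generator emulates the input
contract with known ground truth. The reference conditions: a 64³ grid at
2 mm isotropic spacing, a spherical brain of radius 52 mm (intensity 100),
a 12 mm tumor 18 mm toward the apex (intensity 160), boundaries encoded
with a ~1 mm smooth transition (sub-voxel localization, as partial-volume
averaging would give), additive Gaussian noise with σ = 2% of the
intensity range. Deformations are analytic, compactly supported fields of
the initial coordinates, so increments compose exactly in the linear
regime and every interval's truth field is known in closed form:

* brain shift (I_1→I_2): a Wendland-C2 bump at the brain apex directed
  inward, amplitude 5 mm — within the 4–7 mm range of observed
  intraoperative shift and below 10% of the brain radius (small strains);
* three resections (I_2→I_5) removing 40/70/100% of the tumor volume as
  concentric cavities, each with a radial relaxation field pulling tissue
  toward the cavity (amplitudes 1.5/1.2/1.0 mm, profile 4q(1−q) vanishing
  at the center and the support edge).

Images at later times are generated by exact numerical inversion of the
total map (fixed-point iteration, convergent because the fields are small
and smooth); labels come from the same analytic geometry, so
segmentations are error-free. What the phantom deliberately does **not**
emulate: real anatomy, MR physics and bias fields, segmentation error,
tangential boundary sliding (the shift bump is mostly boundary-normal,
since closest-point surface tracking cannot observe tangential motion).
Passing phantom tests therefore demonstrates the machinery — tracking,
mechanics, enrichment, warping, metrics — under known truth, not clinical
accuracy on real images.

Phantom recovery is evaluated where the method has information: the mean
per-voxel error between predicted and true increment inside a 6 mm
neighborhood of the tracked boundary, per interval; the acceptance run
requires it below the reference in-plane voxel size (0.9375 mm) and
observes ~0.3 mm.

## Numerical and design choices, degenerate inputs

* Duplicate-node tolerance is moot by construction (lattice indices);
  inverted elements are an error, not a warning.
* On-crack evaluation points are perturbed along the crack normal; nodal
  signed values below 1e-12 of a crack edge are moved to the positive side.
* A crack entirely outside the mesh yields an empty enrichment and an
  XFEM system identical to FEM (bit-for-bit assembly).
* A resection interval with no prior cavity falls back to FEM with a
  warning — with boundary data on the entire healthy boundary the results
  are identical anyway.
* The discontinuity for a later resection is the previous image's cavity
  boundary (voxel-mask faces, 5 Laplacian iterations, normals out of the
  cavity), mapped to the initial frame by fixed-point inversion of the
  accumulated displacement interpolated in the mesh.
* Warps are forward splats; holes can only appear under stretches above
  2× voxel pitch and are filled from the nearest covered voxel, logged.
* Determinism: the phantom is seeded; the pipeline itself has no random
  state, so a rerun is byte-identical.

## Problem sizes

The shipped configurations are sized for a single CPU: the reference
phantom meshes to ~11k nodes (~34k DOFs, ~57k tets), a full five-image run
takes about two minutes, and the complete-resection equivalence check uses
a 4 mm mesh of the same phantom geometry. All tolerances quoted above are
asserted in `tests/`, and `scripts/acceptance.py` recomputes every
headline quantity from scratch.

## Known limitations

* Linear kinematics and material only; no force/traction conditions, no
  poroelasticity, no retraction or crack-tip (branch) enrichment.
* Surface tracking observes boundary-normal motion only; purely
  tangential brain motion is invisible to the distance-map forces and is
  recovered only where the ICP pre-alignment captures it rigidly.
* The lattice mesher is intentionally simple (no boundary fitting beyond
  the majority rule); geometric fidelity at the brain surface is half a
  lattice cell.
* The Canny/Hausdorff validation measures edge alignment, not anatomical
  correspondence; it is the appropriate like-for-like comparison across a
  same-protocol series but not an absolute accuracy measure.
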