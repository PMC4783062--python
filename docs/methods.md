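# Methods

This note documents the model and procedure the package implements, the
choices made where the design was genuinely open, what the synthetic
populations do and do not emulate, and the known limitations.

## Superimposition model

A surface is an oriented point set: positions plus unit normals, with an
optional triangulation that is used only for normal computation and
visualization export. All alignment and averaging treats surfaces as
point clouds with normals; this matches the cost function, which uses
only points and normals.

Two surfaces are superimposed by iterating nearest-neighbor pairing and
a rigid solve on the symmetric point-to-plane cost

    C(H, t) = Σ_i ((p_A,i − (H q_B,i − t)) · n_A,i)²
            + Σ_j (((H p_B,j − t) − q_A,j) · n_B,j)²,

with the same motion `y → Hy − t` acting on B's points in both sums.
Point-to-plane residuals make convergence on smooth surfaces far faster
than point-to-point, at the price of leaving tangential sliding weakly
constrained (see Limitations). Because both pairing directions enter one
cost, the minimizing relative configuration does not depend on which
surface is designated as moving.

Implementation choices, in the order they matter:

- **Linearization.** `H ≈ I + [r]×` turns each residual into a row of a
  6-unknown linear least-squares problem in `(r, t)`, solved through its
  6×6 normal equations. The rotation is re-orthonormalized through the
  axis–angle (Rodrigues) map, the standard back-projection for
  linearized rigid solves.
- **Midpoint (swap-antisymmetric) parametrization.** The cross-product
  terms use pair midpoints `(p + q)/2`, and the exact cost used for step
  control splits the motion half-and-half between the surfaces. With
  this, exchanging A and B maps the whole iteration onto its exact
  mirror, and the two directions of superimposition agree to machine
  precision (~1e-16 of the bounding-box diagonal on the test fixtures).
  With the naive "B moves" linearization the two directions diverge at
  second order in the step size and end ~1e-4 of the diagonal apart in
  the flat tangential valley.
- **Damping.** A solved step is halved until the exact cost at fixed
  correspondences does not increase and the angular step is below
  0.1 rad (beyond which the linearization is unreliable). Pure
  linearized ICP can overshoot at large angles.
- **Convergence.** Iteration stops when the relative change of the cost
  falls below `tolerance` (default 1e-6), when `max_iterations`
  (default 100) is reached, or when re-pairing fails to lower the cost —
  the optimum of the discrete pairing landscape has then been reached,
  and this last rule is also what makes the recorded cost trace
  non-increasing, which plain point-to-plane iteration does not
  guarantee across re-pairings.
- **Initialization.** Centroids are matched and the two longest
  principal axes of each surface aligned under all four reflection sign
  combinations (the third axis is always the cross product, so every
  candidate is proper). The candidate with the lowest surface-metric
  value wins, ties to the first. Principal axes require a non-collinear
  point scatter; near-isotropic shapes make the initialization
  arbitrary, which is inherent to the approach.
- **No correspondence rejection.** The entire nearest-neighbor set is
  used, with no distance or normal-compatibility gating. Holes and
  artifacts therefore participate in the alignment — deliberately, so
  that their effect is visible downstream rather than silently masked.

## Procrustes Surface Metric

    D = sqrt( 1/(2 m_A) Σ_i ‖p_A,i − q_B,i‖² + 1/(2 m_B) Σ_j ‖p_B,j − q_A,j‖² )

The square root over the weighted sum is the adopted reading: it makes D
an RMS-style quantity, and it is the only reading under which two
m-point landmark configurations with homologous nearest neighbors
satisfy `D = P/√m` exactly (P the Procrustes distance). `check_eq4`
verifies the identity numerically rather than assuming it; the test
fixtures reach agreement at the 1e-20 level. Summation within each
directed term runs in point order, so `psm(A, B)` and `psm(B, A)` are
bit-identical. PSM is measured point-to-point even though the alignment
cost is point-to-plane — the plane cost is an alignment device, the
metric is the shape distance.

## Prototype estimation

The sample is superimposed to an evolving prototype: every specimen is
ICP-aligned to it; each prototype vertex moves to the arithmetic mean of
its nearest-neighbor matches (one per specimen, no exclusions); vertices
whose matched-index tuples are identical across all specimens are
collapsed to the lowest-index survivor (exact integer comparison, no
coordinate hashing); and the loop ends when the PSM between successive
prototypes falls below tolerance (default 1e-4 × the prototype's
bounding-box diagonal, a value the convergence traces comfortably cross)
or after `max_outer_iterations` (default 5 — on the synthetic
populations three to four iterations suffice, consistent with the mean
surface stabilizing quickly).

Two choices deserve emphasis:

- **Gauge anchoring.** The averaging step is defined only up to a rigid
  motion of the whole configuration: the specimens re-align to wherever
  the prototype goes, so an un-anchored prototype can drift rigidly at a
  constant rate forever while its shape never changes (observed as a
  uniform ~1e-3 per-iteration translation at some seeds). Each updated
  prototype is therefore rigidly aligned back onto its predecessor
  (Kabsch on the 1:1-corresponding vertices, before deduplication) —
  the same reason classical GPA fixes its mean's pose. The
  prototype-change metric then measures pure shape change.
- **Continuation.** In outer iterations after the first, each specimen's
  ICP continues from its previous pose rather than re-initializing;
  the fixed-point property (a sample of identical aligned copies leaves
  the prototype unchanged) is preserved and redundant reflection
  searches are avoided. After the loop, one final alignment pass against
  the final prototype makes the stored pairings and per-specimen PSM
  values mutually consistent.

The prototype is treated as a point cloud after the first update:
normals are re-estimated by local plane fitting, and faces are carried
along (with triangles referencing removed vertices dropped) only for
visualization export. Surface collapse — duplicate removal shrinking
high-variance regions — is inherited method behavior, not repaired here.

## Statistics

The stored pairings give the homologized matrix: N specimens ×
3V coordinates of each specimen's match to each final-prototype vertex.

- **Pointwise variance** is the trace of the per-vertex 3×3 covariance
  of matches across specimens (unbiased, N−1 divisor) — a
  rotation-invariant total variance in squared length units, exported as
  a blue→red heat map on the prototype.
- **Ordination** computes principal axes through the N×N Gram matrix of
  centered rows (specimen space) and maps eigenvectors back to
  coordinate space, avoiding any 3V×3V object; it agrees with direct
  covariance PCA to 1e-13 on every instance small enough to check both
  ways. Axis signs are fixed by making each axis's largest-magnitude
  coordinate positive. K defaults to min(N−1, 10).
- **Vertex regression** fits, per vertex, an ordinary least-squares
  slope of its coordinates on one score vector; coloring is the squared
  slope magnitude, min–max scaled to [0, 1]. The specimens with extreme
  scores on an axis are identified for display against the mean surface.

## Synthetic populations

The generator produces what the estimator assumes: quasi-uniform
triangulated ellipsoids (subdivided icosahedron; default semi-axes
3×2×1, ~642 vertices — desk-scale stand-ins for real scans' 10⁵–10⁶
points), per-specimen localized deformations, isotropic Gaussian
coordinate noise, optional cap-shaped holes, and known random rigid
motions (≤20°, translations ≤0.5 by default). Everything is reproducible
from the seed, and the sampled amplitudes and motions are returned as
ground truth.

Condition choices: the default noise σ is 0.2% of the bounding-box
diagonal, matching the relative precision of the desktop laser scanners
such data come from (≈0.1–0.25% of specimen size). Bump amplitudes are
drawn from U(0, 0.4) — shape variation up to ~5% of the diagonal. Two
falloff profiles exist: a raised-cosine dome, and a "plateau" profile
(flat core, thin cosine skirt) for assertions that need a crisply
bounded deformed region; an `antipodal` option applies the same lobe at
the opposite pole with the same amplitude, giving a deformation field
with nearly zero net rigid component.

What the generator does **not** emulate: real anatomy, nonuniform point
density, scanning artifacts other than holes, outliers, or
non-rigid/allometric variation. Passing tests therefore demonstrate the
algorithmic properties (recovery, symmetry, convergence, localization)
under clean conditions, not robustness to everything real scans do.

## Limitations

- A deformation field with a nonzero rigid projection (e.g. a single
  off-axis bump) necessarily bleeds into the superimposition: part of
  the planted signal appears as global pose jitter, inflating background
  variance and regression slopes everywhere (the morphometric
  "Pinocchio" effect). This is a property of superimposition methods,
  not an implementation defect; the localization tests use
  rigidly-balanced fields precisely to separate the two effects.
- From an already near-optimal pose, minimizing the plane cost can
  slightly increase the point-to-point PSM (the two objectives differ);
  PSM improvement is guaranteed only relative to a coarse start.
- Orientation identifiability is the user's responsibility: a specimen
  whose shape is (near-)symmetric — an almost undeformed ellipsoid, or a
  weakly-featured scan with a large hole — can be initialized in a
  reflected pose, and nothing downstream can correct it. Choose
  prototypes and prepare scans accordingly.
- With high sample variation, nearest-neighbor homology degrades and the
  final prototype depends increasingly on the initial prototype choice;
  this is documented behavior, demonstrated in the test suite.
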