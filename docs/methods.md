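# Methods

## Problem and model

The package plans where to implant fiducial markers so that the
CyberKnife stereoscopic imaging chain (two oblique kV views at ±45°
about the Z axis) can track a superficial tumor. A plan is a set of
k ≥ 3 marker positions `gᵢ = (xᵢ, yᵢ, zᵢ)` in the DICOM patient
coordinate system (LPS, millimetres, Z superior–inferior) satisfying:

* pairwise separation `‖gᵢ − gⱼ‖ ≥ d_min` (default 18 mm);
* every interior angle of every marker triangle ≥ `theta_min`
  (default 30°; the vendor manual's floor of 15° is available as the
  `ConstraintConfig.manual_floor()` preset — the 30° default leaves
  headroom against post-implantation marker migration);
* each marker within `d_tumor_max` (default 50 mm) of the tumor
  centroid, so marker and tumor move together;
* marker depth above the tumor surface within `band` (default
  20–30 mm), keeping implantation superficial;
* no two markers closer than `overlap_extent` (default 5 mm, a typical
  gold-fiducial length) in either oblique projection.

## Candidate surface

Candidates are sampled from a clamped tensor-product B-spline surface
fitted to a cloud around the tumor. Degrees default to cubic (p = q =
3) with uniform interior knots on [0, 1] — the standard smooth-surface
choice. Scattered clouds get cylindrical parameters about the longest
principal component of the cloud: u = azimuth / 2π, v = normalised
axial coordinate. The surface is not periodic in u; the azimuthal seam
is accepted (seam candidates are still valid markers) because it keeps
the fit an ordinary linear least-squares problem.

Control points solve `min Σₖ ‖Pₖ − S(uₖ, vₖ)‖²` via orthogonal
factorisation (`scipy.linalg.lstsq`), never normal equations. With
fewer points than control points, or a rank-deficient collocation
matrix and zero smoothing, the fit raises an error advising a smaller
grid or `smoothing > 0`; positive smoothing adds a Tikhonov penalty on
second differences of the control grid (rows and columns). The
reported residual `E` always excludes the penalty. Refitting exact
samples of a cubic surface with a matching 6×6 grid recovers the
control points to 1e-6 mm with residual below 1e-10 mm² (asserted in
the tests, together with partition of unity to 1e-12, affine
invariance, and the convex-hull property checked by linear
programming).

Pipeline defaults: 6×6 control grid, 8×8 candidate sampling
(64 candidates). That grid is rich enough to produce thousands of
feasible triples on the reference phantom while keeping the exhaustive
cross-checks below cited in easy reach.

## Filters and enumeration

* **Z band**: keep candidates with |z − tumor mid-z| ≤ half-width
  (inclusive). The source procedure leaves the threshold unquantified;
  the default is half the tumor's Z extent plus 10 mm.
* **Proximity**: centroid distance ≤ 50 mm and surface distance within
  the band, both inclusive. Surface distance is measured as
  nearest-neighbour distance to the tumor cloud (kd-tree), which
  overestimates the true point-to-surface distance by O(spacing²) at
  finite sampling density (~0.1 mm for 500 points on a 15 mm sphere).
  Annotations already cached on a `CandidateSet` are trusted, so exact
  distances (e.g. a phantom's construction offsets) can be supplied.
  The band is measured to the tumor *surface* and the 50 mm rule to
  the *centroid*; both values are cached per candidate.
* **Distance graph**: edge iff distance ≥ d_min, inclusive — the
  displayed inequality wins over pseudocode that prints a strict one.
  Because the "far" graph is dense, the kd-tree finds the sparse
  complement (pairs *closer* than d_min, with pairs at exactly d_min
  re-checked and kept as edges); the result equals the all-pairs
  construction exactly, which the tests assert.
* **Enumeration**: default mode returns every k-subset of every
  maximal clique, which for triples is exactly the set of triangles of
  the graph; triangles are enumerated directly from the adjacency
  matrix. For k > 3 an ordered DFS enumerates k-cliques and the angle
  rule is applied to every 3-subset. Strict-paper mode instead runs
  Bron–Kerbosch (`networkx.find_cliques`) and keeps only maximal
  cliques of size exactly k — the literal published procedure, which
  misses valid triangles embedded in larger cliques and, on dense far
  graphs, can be exponentially expensive (a complement of n/2 disjoint
  close pairs yields 2^(n/2) maximal cliques); it is therefore meant
  for small candidate sets and is exercised on such in the tests,
  where its output is verified to be a subset of default mode's.
* **Oracle**: `brute_force_plan` enumerates all C(n, k) subsets and
  applies the distance and angle rules directly. Default-mode
  enumeration must match it exactly (index lists and cached metrics);
  the suite checks 20 random instances up to n = 200 plus the full
  pipeline's candidate sets.

Determinism: candidate order follows the (u, v) sampling grid; set
lists are sorted lexicographically by candidate index; collinear
triples are rejected naturally by the angle filter (0° < 30°), not
special-cased. All phantom randomness flows from a single seeded
`numpy` generator, so a spec (seed included) reproduces a plan bit for
bit.

## Projection model

Each view rotates the markers about Z by the view angle (after
translating the tumor centroid to the origin) and projects
orthographically. The literal recipe — project onto the X–Y plane
after rotating about Z — cannot distinguish the two views, because a
rotation about Z is an isometry of the X–Y plane; the test suite
asserts this inertness. The default convention therefore treats each
imager's beam as the rotated Y axis and keeps (rotated-x, z)
coordinates, which matches the stereoscopic geometry of two
ceiling-mounted sources; the literal mode remains available behind
`literal_projection` for traceability. Projection is parallel
(orthographic); divergent-beam triangulation is out of scope. Overlap
is strict (< extent): projections exactly one fiducial length apart
still count as distinguishable.

## Rubric

Criteria: markers within 50 mm of the centroid (1→1, 2→2, ≥3→3 pts),
all angles meeting 30° (2 pts), all distances meeting 18 mm (2 pts),
markers free of overlap in every view (1→1, 2→2, ≥3→3 pts); total 10.
At exact thresholds points are awarded, so any set accepted by the
inclusive planner scores 10 — the consistency the published compliant
cases exhibit; `strict_rubric` switches to strict inequalities. Zero
qualifying markers on the counting criteria has no rubric row and
scores 0 with a warning. The proximity criterion measures to the
centroid, matching the constraint it mirrors.

## Phantom generator

`generate_phantom` emulates the anatomy the planner targets: an
ellipsoidal tumor surface (default a 15 mm sphere at the origin,
500 points, optional isotropic Gaussian noise, default sd 0) and a
candidate shell offset 20–30 mm along the outward surface normal —
exactly the stated depth band, since offsetting a convex surface along
its outward normal by t leaves the point t mm from the surface (the
tests verify this against an independent numerical point-to-ellipsoid
minimisation). Directions are drawn uniformly on the unit sphere and
scaled to the ellipsoid, which is area-uniform for spheres and mildly
non-uniform for eccentric ellipsoids — irrelevant to the constraints
being exercised. What the phantom does *not* emulate: real skin
topology, organ boundaries or implantation-path feasibility,
CT/contouring noise, or marker migration. Passing on phantoms
demonstrates the geometry engine, not clinical validity on patient
anatomy.

## Problem sizes and limitations

The reference runs use 500-point clouds, a 6×6 control grid, and 64
sampled candidates, giving a few thousand feasible triples in well
under a second per phantom; exhaustive oracle comparisons go up to 200
candidates (~1.3 million subsets, vectorised in chunks). Known
limitations: no organ-at-risk or needle-path planning; no NURBS
weights or trimmed surfaces; the u seam of the open surface slightly
distorts the candidate spacing near azimuth 0; cylindrical
parameterization degrades near the poles of closed shells, where the
clamped surface edge averages pole-region points — such candidates are
usually removed by the proximity band. Marker sets larger than 3 are
supported via `set_size`, but redundancy optimisation among 4–6
markers is not attempted.
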