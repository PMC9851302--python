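# Methods

## The remeshing model

`voxmesh` treats watertight surface reconstruction as a volumetric
resampling problem.  Any input — triangle soup, grayscale or binary
volume, morphology skeleton — is reduced to a common intermediate, a
uniformly sampled occupancy grid, and the output surface is extracted
from that grid.  The output's integrity therefore depends only on the
grid, never on the connectivity of the input; fragmented, overlapping,
self-intersecting or punctured inputs are handled transparently because
rasterization is a purely local, idempotent set-union operation.

The price of this robustness is a systematic geometric bias.
Conservative rasterization sets every voxel a triangle *touches*, so the
voxelized solid extends beyond the true surface by up to one voxel
(measured: ≈0.7 voxel radially on spheres, ≈1 voxel on grid-aligned flat
faces).  At resolution *r* voxels/μm this bounds the Hausdorff error by
~2 voxels and inflates enclosed volume by roughly `3·(0.7/r)/R` for a
feature of radius `R` μm.  At the standard operating point of 5
voxels/μm, cell-scale objects (R ≳ 9 μm) stay within 5% volume error;
subcellular work should use the 10 voxels/μm preset.  This bias is a
property of the method, not a defect of the implementation: the
convergence quantities in `scripts/acceptance.py` show it halving as
resolution doubles.

## Grids

Grids are isotropic (`voxel_size` μm), 0-based, with voxel `i` covering
the half-open world interval `[origin + i·h, origin + (i+1)·h)`.
Occupancy serializes at one bit per voxel (LSB-first, x fastest, then y,
then z; the ASCII header states this).  The bit-packing order is this
package's convention — the on-disk BIT format is self-describing but not
claimed to be byte-compatible with any other tool.  All pipelines pad
the grid by 2 voxels per side so the surface shell never touches the
boundary, leaving the flood fill an exterior corridor and guaranteeing
closed extraction.

## Solid voxelization

Interiors are filled per 2D slice: pixels not reachable from the slice
border through unset pixels are interior (4-connected exterior
propagation, so 8-connected diagonal shell corners do not leak).  Each
slice is a pure function of itself — the parallelism contract: any
execution order, or full parallelism, produces identical grids.

Single-axis filling wrongly fills through-holes aligned with the fill
axis (a torus filled along its symmetry axis loses its hole).  Three-way
mode fills along x, y and z and ANDs the three solids, then ORs the
original shell back so one-voxel-thick features survive.  Every
through-hole is open along at least one axis, so holes of any
orientation survive the AND.  Shell gaps below ~2 voxels close during
conservative rasterization; wider gaps leak the slices that see them,
which the AND then excludes from the interior — the extracted surface is
still closed and (for cap-like punctures) genus-0, but the enclosed
volume loses the leaked slabs.  Gap repair is therefore a *topological*
guarantee, not a volumetric one.

## Isosurface extraction

Bit grids are sampled at voxel centers with values {0,1} and contoured
at 0.5, so vertices land on voxel-face midpoints.  Marching cubes
delegates to scikit-image's topologically consistent variant: ambiguous
cube configurations are resolved so padded solids always yield closed
2-manifolds, which serves the watertightness contract directly (the
classic fixed-table formulation can emit cracks that would have to be
caught downstream).  The dual extractor is uniform-grid dual contouring:
one vertex per sign-crossing cell at the mean of its edge crossings (no
QEF, no adaptivity), one quad per sign-crossing grid edge, split into
two triangles along the shorter diagonal.  Vertex placement differences
between the two extractors are erased by smoothing and optimization;
only the topology contract is load-bearing.

On binary fields both extractors can emit exactly-touching sheets at
diagonally-adjacent voxel configurations.  These register as
self-intersections under the ε-tolerant triangle test; the smoothing
pass separates them, which is why smoothing precedes verification.

## Smoothing

Two-phase cotangent Laplacian smoothing.  Per vertex,
`k(v) = Σ_u w_uv (u − v) / Σ_u w_uv` with `w_uv` the mean of the two
cotangents opposite edge (u,v) (one cotangent on boundary edges, weights
clamped to ≥ 1e-6 so obtuse one-rings cannot reverse the kernel).  Each
iteration applies `v ← v + λ·k(v)` and, if `μ < 0`,
`v ← v + μ·k(v)` with the kernel recomputed at the moved positions.
Defaults λ = 0.6, μ = −0.55: the classical smooth/inflate pairing in
which the negative phase dampens the volume shrinkage pure Laplacian
smoothing causes on closed surfaces.  Boundary vertices (open inputs)
are frozen.  Connectivity is rebuilt only between iterations.

## Adaptive optimization

Per iteration: (a) *flat coarsening* — manifold edges whose two incident
triangles deviate by less than `flat_angle` (default 8°) are collapse
candidates; (b) *dense coarsening* — edges shorter than
`min_edge_length` (default 0.1·voxel) likewise; candidates are processed
shortest-first with ties broken by vertex index (deterministic), each
collapse checked against the edge link condition, a 90° normal-flip
bound and closedness, so a closed manifold stays one; (c) *normal-based
smoothing* — vertices move toward the area-weighted average plane of
their one-ring, which flattens staircase remnants without moving crease
vertices (a vertex on all its incident planes has zero offset).
Collapse placement is the edge midpoint, except when exactly one
endpoint lies on a crease (incident dihedral > 30°): then the crease
vertex survives unmoved.  Midpoint-only placement measurably rounds box
edges (−2.1% volume on the box fixture); feature-aware placement keeps
the loss under 2%.  Triangle count never increases.

## Watertightness verification and repair

A mesh is watertight iff self-intersections = non-manifold edges =
non-manifold vertices = boundary edges = 0.  Floating vertices are
reported and stripped but do not break the definition (they carry no
surface).  Detector conventions: boundary edge = incidence 1;
non-manifold edge = incidence ≥ 3; non-manifold vertex = incident
triangles not forming one edge-connected fan; self-intersection = a
non-adjacent triangle pair whose closed triangles intersect (ε = 1e-9 on
parametric coordinates; shared-vertex pairs excluded).  The accelerated
intersection search (uniform spatial hash sized at the 90th-percentile
triangle extent, grown until covered-cell totals are O(m)) is
output-identical to the all-pairs test, which the test-suite asserts on
random soups.

Repair iterates: weld vertices closer than 1e-6 μm → drop
degenerate/duplicate triangles → on ≥3-incidence edges keep the two
lowest-index triangles → split non-manifold vertices (one copy per fan
component) → delete self-intersecting triangles, widening the excision
by one vertex ring per round so oscillating patch/intersect cycles
terminate → fill boundary loops smallest-first by ear clipping in the
PCA plane (loops over 200 edges abort with advice to re-voxelize:
geometric filling of large gaps distorts shape).  If a partition cannot
be repaired after optimization, the pipeline falls back to the
unoptimized smoothed surface, and as a last resort pushes the partition
through the voxel engine again (three-way).  The repair loop either
returns a mesh passing the four-zero test or raises with the last
report — there is no silent partial repair.

## Morphology synthesis

Skeleton repair interpolates zero radii linearly along arc length,
merges coincident consecutive samples, and median-filters (window 3)
radius sequences of sections with ≥5 samples.  Adaptive resampling keeps
a sample only when it is farther from the last kept sample than that
sample's radius; endpoints are never moved.  Paths are resampled with
cubic Hermite segments whose tangents come from the centripetal
Catmull–Rom formulation (α = 0.5, knot spacing `|Δp|^α`, one-sided at
endpoints); radii interpolate linearly in arc length.

Tubes sweep a circle of `n_ring` vertices (default 16) per path point in
the plane normal to the local tangent; frames are parallel-transported,
so the tube never twists, and rings are stitched 1:1 since the vertex
count is constant.  Acyclic morphologies use per-path proxies (every
root-to-leaf path, depth-first, soma centroid prepended so no gap opens
at the soma); cyclic vascular graphs use per-section proxies with a
packing icosphere at every branch point, radius equal to the largest
terminal-sample radius meeting there.

The soma is a surrogate, not a biophysical model: a subdivision-3
icosphere at the soma centroid with the mean soma radius (mean distance
from the type-1 centroid to the first samples of root neurites), pulled
toward each soma-connected neurite over a spherical cap of angular
radius `asin(min(1, r_segment/r_soma))`, then uniformly rescaled about
the centroid so enclosed volume is restored exactly (the cube-root
scale).  It reproduces the two stated contracts — plausible bulging
toward neurites and volume preservation within 1% — and nothing finer.

Astrocyte endfeet arrive as a JSON sidecar (vertices, per-vertex
thickness, triangles); patch edges longer than the local thickness are
midpoint-subdivided (longest offending edge first), and the implicit
endfoot surface is rasterized as a union of spheres of radius
thickness/2 at vertices and along edges at ≤ voxel/2 spacing.  After
extraction, only the largest-area partition (the membrane) is kept.

SWC conventions: contiguous type-1 samples form the soma; neuron kind
requires an acyclic graph; vasculature kind merges samples at identical
coordinates into one node, which is how closed loops are written in a
single-parent format — the same coincidence in neuron kind is a cycle
error.  A `--swc-diameter` flag halves loaded radii for datasets that
store diameters.

## Synthetic data

The fixture battery is the package's model of its real inputs: deleted
and duplicated faces, jittered corners and shifted overlapping copies
emulate the defect classes of segmented EM meshes (fragmentation, gaps,
self-intersection); generated neurons are tapering binary trees with a
type-1 soma block; vessels are rings with bridges giving an exact cycle
rank; masks are lattice balls with exactly countable occupancy.  What
the battery does *not* emulate: EM noise statistics, realistic spine or
bouton geometry, anisotropic section artifacts, or the tessellation
style of any particular segmentation pipeline.  Passing it demonstrates
the engine's contracts (watertightness, topology, convergence) on the
defect classes, not segmentation-specific accuracy.

Fidelity checks run on cell-scale smooth shapes (sphere r = 10 μm,
ellipsoid 12×10×8 μm) at 5 voxels/μm with 5 optimization iterations;
the sizes put the known rasterization bias inside the 5% volume budget,
which is exactly how the operating point is meant to be chosen in
practice.  The battery itself runs at 4 voxels/μm on ~2 μm objects to
keep the full sweep fast; watertightness and topology do not depend on
scale.

## Numerical choices

Weld tolerance 1e-6 μm (float32 interchange formats quantize at ~1e-7
relative).  Triangle-box overlap uses the 13-axis separating-axis test
with ε = 1e-12; touching counts as overlap.  Triangle-triangle
intersection uses Möller interval tests with ε = 1e-9 and an explicit
coplanar 2D branch.  Point-in-mesh uses even-odd ray parity along a
fixed irrational direction so axis-aligned geometry cannot graze.
Point-to-surface distances are exact per triangle (interior projection
vs. three edge segments), with a k-nearest-centroid bound certified
against the maximum triangle circumradius.  Enclosed volume orients each
partition by propagation from a seed triangle and takes the absolute
signed-tetrahedron sum, so input winding is irrelevant.

## Known limitations

- The conservative-rasterization volume bias (≈0.7 voxel outward) is
  uncorrected; choose resolution relative to feature size.
- Single-axis solid filling is wrong for axis-aligned through-holes by
  construction; three-way mode exists for that and is the vascular
  default, but mesh-pipeline users must opt in (`--solid three-way`).
- Wide shell gaps (> ~3 voxels) are closed topologically, not
  volumetrically: leaked slices are excluded from the interior.
- Dual contouring is non-adaptive and QEF-free; sharp features are
  recovered by the optimizer's crease handling, not by the extractor.
- Repair is heuristic; its guarantees are "watertight or raise", with
  re-voxelization as the terminal fallback, not minimal-change mesh
  surgery.
- Tetrahedral inputs only have their boundary extracted; no tetrahedral
  meshes are generated.
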