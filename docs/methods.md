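# Methods

## Problem setting

Micro-CT scans of mature seed pods are 3D grayscale stacks (one 2D slice
per page; axis order Z, Y, X with Z the pod's long axis). Phenotyping
asks for the number of seeds per pod, each seed's location, size and
shape, and each seed's position within the pod: which of the two valves
(the chambers on either side of the pseudoseptum membrane) it occupies,
its order from the beak end to the pedicel end, and its spacing to the
neighboring seed in the same valve.

## Star-convex seed representation

Seeds are rounded-to-ovate, so each is modelled as a star-convex
polyhedron: a center voxel plus radial distances to the boundary along a
fixed set of n unit directions. Directions are the golden-angle
(Fibonacci) spherical lattice, z_k = 1 − 2(k+½)/n and azimuth
θ_k = k·π(3−√5), which is approximately equal-area on the sphere. When
the seed population is anisotropic, each lattice vector is divided
component-wise by the per-axis anisotropy factors and renormalized; this
shifts ray density toward the population's long axis so an ellipsoid
with those axis ratios is evenly covered.

*Distance extraction* marches from the center along each ray in 0.5-voxel
steps (nearest-voxel membership test) and refines the inside/outside
crossing by bisection to step/16. The 0.5-voxel step is far below the
≥ 20-voxel seed scale; halving it changes extracted distances by less
than the voxelization error.

*Rasterization* sets voxel v iff |v − c| ≤ r(û), where r(û) interpolates
the per-ray distances barycentrically over the spherical triangulation
given by the convex hull of the ray directions (the query direction is
intersected with the hull surface; the face's barycentric weights are
clipped to non-negative and renormalized to guard against degenerate
faces). All-zero distances produce exactly the center voxel. At least 4
rays are required (otherwise no triangulation exists).

*Reconstruction center.* The centroid of a concave instance can fall
outside it, so reconstruction uses the interior voxel nearest the
centroid — a single representative center per seed.

*Anisotropy estimate.* Per axis, the median bounding-box extent over all
instances; the factor for an axis is the largest median divided by that
axis's median, so the longest axis has factor exactly 1. Rectangular
boxes with median extents (32, 31, 29) reproduce factors
(1.0, 1.032258…, 1.103448…).

## Detection

The detector is deliberately classical and training-free: it exercises
the same candidate → NMS → label pipeline that a learned star-convex
predictor feeds, and every downstream stage also accepts imported label
volumes from any external model (`import_external_labels`, which
relabels to 1..k in order of first appearance).

1. Binarize by a fixed intensity value or Otsu's threshold.
2. Euclidean distance transform of the foreground; every 26-connected
   local maximum (plateaus merged to their most central voxel) becomes a
   candidate center with score = its distance value / global maximum.
   Thin structures such as the pod wall score low and are removed by the
   score threshold.
3. Per-candidate radial distances are extracted from the binary mask.
4. Greedy non-maximum suppression in descending score order (ties broken
   by center lexicographic order): a candidate is kept iff its
   rasterized-polyhedron IoU with every already-kept candidate is at
   most the NMS threshold. Note the convention: *suppress when overlap
   exceeds the threshold*, i.e. a **lower** threshold prunes more
   aggressively. The opposite reading ("higher = more pruning") exists
   in the literature; this package implements and tests the standard
   convention stated here.
5. Survivors are rasterized into a label volume, labels 1..k in
   descending score; contested voxels go to the higher-scoring instance;
   instances below the minimum volume are dropped and labels
   re-compacted.

`optimize_thresholds` grid-searches (score threshold, NMS threshold)
against validation ground truth, maximizing mean F1 over the τ grid
0.1–0.8, with ties broken toward the smaller NMS then smaller score
threshold. It is deterministic for fixed inputs.

## Evaluation metrics

Predictions and ground truth are matched one-to-one at IoU threshold τ
using the maximum-total-IoU assignment (Hungarian algorithm on the joint
label histogram's IoU matrix, pairs below τ excluded). For τ ≥ 0.5 at
most one prediction can exceed τ per ground-truth instance, so greedy
and optimal matching provably coincide; below 0.5 the optimal assignment
provides the deterministic rule. From TP = |matches|, FN = n_true − TP,
FP = n_pred − TP:

- recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = harmonic mean;
- mean matched score = (Σ matched IoU)/TP;
- mean true score = (Σ matched IoU)/n_true;
- panoptic quality = (Σ matched IoU)/(TP + FP/2 + FN/2).

Every 0/0 is defined as 0. These identities hold exactly:
mean_true = mean_matched·TP/n_true and PQ = mean_matched·TP/(TP+FP/2+FN/2).

## Shape measurements

Per instance (bounding boxes half-open [min, max), 0-based voxel
coordinates; the half-open convention makes extent = volume/bbox_volume
an exact ratio):

- volume = voxel count; bbox volume = Π(max−min); extent = V/bboxV;
- convex volume = voxels inside the 3D convex hull image; solidity =
  V/convexV;
- equivalent diameter = (6V/π)^(1/3) — the **equal-volume sphere's**
  diameter. (A 2D equal-area-circle reading of "equivalent diameter" is
  inconsistent with the 3D volumes being measured; the sphere formula is
  the one whose values are internally consistent with the rest of the
  report.)
- surface area = triangle area of the marching-cubes isosurface at level
  0.5, computed on the binary mask padded by 2 voxels and Gaussian
  anti-aliased with σ = 0.5 voxel. A raw staircase isosurface of a
  voxelized ball overestimates the analytic area by ~9% (sphericity
  0.918 for r = 15); σ = 0.5 brings it to within ~4% (sphericity 0.961)
  while a side-21 cube stays within 5% of its closed form (π/6)^(1/3) ≈
  0.806. Larger σ would start rounding genuine shape detail.
- sphericity = π^(1/3)(6V)^(2/3)/SA;
- major/minor axis length = 2√(5λ) for the extreme eigenvalues λ of the
  voxel-coordinate covariance (for a solid ellipsoid with semi-axis a,
  the coordinate variance is a²/5, so the length recovers 2a). These are
  orientation-dependent and validated by property tests (ellipsoid
  recovery, ordering) rather than against any fixed reference rows.

## Valve sorting

With the pod's long axis along Z, seed centroids in the (Z, X) plane
form two bands around the pseudoseptum. X-centroid is regressed on
Z-centroid with Cleveland's lowess: per point, a weighted linear fit
over the ⌈f·n⌉ nearest neighbors with tricube distance weights, followed
by 3 robustifying passes with bisquare weights of residuals scaled by 6
× median |residual|. The smoother span is f = 1 for pods with ≤ 5 seeds
(too few points to localize) and f = 2/3 otherwise (the classical
default of the reference lowess implementations), both overridable.

Sign of the residual x − x̂ assigns the valve: positive → valve 1,
negative → valve 2, exactly zero → valve 1 (fixed tie-break). Within a
valve, seeds are ordered by ascending Z (beak → pedicel) and spacing is
the Euclidean distance between consecutive same-valve centroids in the
(Z, X) plane (the planar rather than 3D distance; Y scatter within a
valve is small compared to Z spacing, so the two differ negligibly).
Because which chamber is "valve 1" depends on scan orientation,
accuracy against ground truth is scored up to the valve-label swap.

This graphical method needs enough centroids to localize the septum:
phantom studies here reproduce the expectation that pods with ≥ 7 seeds
sort reliably (mean accuracy ≥ 0.90 over 30 replicates) while very
sparse pods are intrinsically ambiguous.

## Pod phantom

The generator emulates the structure of real pod scans at reduced scale
so the full pipeline runs in seconds: default volume 256×128×128
(configurable up to scan scale, where real stacks are 505–1397 slices
of 512×512), pod axis along Z, a smooth polynomial pseudoseptum curve
x(z), a thin cylindrical pod-wall shell following the curve, and three
intensity levels (background 20, wall 90, seed 200) with additive
Gaussian noise (σ = 8, i.e. seed-to-background SNR 22.5).

Seeds are star-convex by construction: radius function = ellipsoid
radius (base radius 10–18 voxels, giving 20–36-voxel extents; per-axis
scales default to the 32:31:29 Z:Y:X extent ratio) × (1 + a smooth
even quadratic directional series with amplitude capped at 0.15,
normalized so the cap is exact). The amplitude cap keeps radii positive,
hence bodies star-convex — required for the reconstruction bounds to be
meaningful.

Placement packs seeds sequentially along Z: valves alternate with a 15%
chance of repeating the previous valve (mirroring ovule alternation
along the replum with occasional same-side neighbors), X offsets sit
±12 voxels (±2 jitter) off the septum curve, and consecutive Z
positions advance just far enough that every pairwise center distance
exceeds the sum of maximal radii plus 2 voxels (verified for all pairs;
bounded retries, then an error). Valve truth is the side of the
generating curve; labels are 1..n in ascending Z. `generate_study`
draws per-pod seed counts from a range and grows the Z extent with the
count, as taller real stacks hold more seeds; per-pod RNG seeds are
spawned from the master seed, so cohorts are reproducible.

What the phantom does **not** emulate: beam-hardening/ring artifacts,
partial-volume gradients at seed boundaries, aborted/shriveled seeds,
touching seeds, or pod curvature in Y. Consequently, perfect phantom
detection scores demonstrate the correctness of the pipeline's
plumbing — candidate extraction, suppression, matching, measurement —
not expected performance on real scans, where a learned detector
supplies the segmentation via `import_external_labels`.

## Problem sizes and determinism

Default test and acceptance runs use pods of 6–9 seeds in 256–420-slice
volumes, 20 detection replicates, 30 valve replicates and 50
reconstruction seeds; these sizes give stable statistics while keeping a
full run in the minutes range on one CPU. All stochastic steps take
explicit RNG seeds; identical configurations reproduce bit-identical
volumes and tables.
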