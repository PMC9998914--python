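# podstar

Automated seed phenotyping for 3D micro-CT scans of seed pods (e.g.
*Brassica napus*). Given a volumetric scan whose long axis runs along the
slice (Z) axis, the pipeline

1. **detects and segments seeds** as *star-convex polyhedra* — each seed is
   a center voxel plus radial boundary distances along a Fibonacci ray
   lattice — using a classical detector (intensity threshold → distance
   transform maxima → score filter → non-maximum suppression), or imports
   label volumes produced by any external model;
2. **evaluates** predictions against ground truth with one-to-one IoU
   matching at thresholds τ: TP/FP/FN, precision, recall, F1, mean matched
   score, mean true score and panoptic quality;
3. **measures** every seed: bounding box, centroid, volume, sphericity,
   surface area, convex volume, equivalent diameter, extent, axis lengths,
   solidity;
4. **sorts seeds into the pod's two valves** by fitting a robust lowess
   curve to the seed centroids in the (Z, X) plane as a stand-in for the
   pseudoseptum membrane, then sequences seeds beak→pedicel per valve and
   reports inter-seed spacing.

A synthetic **pod phantom** generator produces CT-like volumes with known
seed labels, valve membership and sequence order, so the whole pipeline can
be exercised and benchmarked without scan data.

## The core representation

A body is star-convex about a center **c** if every boundary point is
visible from **c**; it is then fully described by its radius function
r(**û**) sampled along n fixed unit directions. Directions come from the
golden-angle spherical lattice z_k = 1 − 2(k+½)/n, θ_k = k·π(3−√5)
(approximately equal-area), optionally warped by per-axis anisotropy
factors a = (a_Z, a_Y, a_X) (each lattice vector divided component-wise by
a and renormalized) so an ellipsoid with those axis ratios is evenly
covered. Reconstruction rasterizes the polyhedron by barycentric
interpolation of the per-ray radii over the spherical triangulation of the
ray directions. On rounded/ovate phantom seeds the reconstruction IoU
exceeds 0.8 with as few as 32 rays and 0.9 from 64 rays up.

Matching uses IoU = |A∩B|/|A∪B| with the optimal one-to-one assignment;
panoptic quality is Σ matched IoU / (TP + FP/2 + FN/2).

## Worked example

```sh
python examples/02_detect_and_evaluate.py
```

```
6 seeds detected (6 in the ground truth)

 tau  tp  fp  fn  precision  recall  f1  mean_matched_score
 0.1   6   0   0        1.0     1.0 1.0               0.966
 0.5   6   0   0        1.0     1.0 1.0               0.966
 0.9   6   0   0        1.0     1.0 1.0               0.966
```

Every phantom seed is found exactly once at every matching threshold
(F1 = 1.0), and matched detections overlap the true seed masks by 96.6%
of voxels on average. `examples/01_reconstruction_accuracy.py`,
`03_measure_seeds.py` and `04_sort_valves.py` walk the other stages;
`04` prints the per-valve sequence/spacing table and a valve accuracy of
100% on a 9-seed phantom.

The same stages are available from the shell:

```sh
podstar simulate --out-dir pods/ --n-pods 3 --n-seeds 4:9 --seed 1
podstar detect --image pods/pod000_image.tif --labels-out pred.tif --threshold 145
podstar evaluate --gt pods/pod000_labels.tif --pred pred.tif --out metrics.csv
podstar measure --labels pred.tif --out seeds.csv
podstar sort-valves --seeds seeds.csv --out valves.csv
podstar reconstruct-eval --labels pods/pod000_labels.tif --out recon.csv
```

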