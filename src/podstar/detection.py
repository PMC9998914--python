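"""Training-free star-convex seed detector.

The detector binarizes the intensity volume (fixed value or Otsu),
computes the interior Euclidean distance transform, and turns every
26-connected local maximum of the transform (plateaus merged) into a
candidate star-convex instance whose per-ray boundary distances are read
off the binary mask.  The candidate's confidence is its distance-transform
value normalized by the global maximum — deep interior points of large
blobs score near 1, thin structures (pod wall, noise specks) score low.

Candidates then pass a score threshold and greedy non-maximum
suppression: visiting candidates in descending score, a candidate is kept
only if its rasterized polyhedron overlaps every already-kept candidate
with IoU <= nms_threshold (suppress-when-overlap-exceeds convention).
Survivors are rasterized into a label volume.

Any externally produced label volume (e.g. a neural-network segmentation)
can be imported instead, so every downstream stage is detector-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import RaySet, StarConvexInstance, boundary_distances, fibonacci_rays, rasterize
from .io import ImageVolume, LabelVolume, read_volume

__all__ = [
    "DetectionConfig",
    "CandidateSet",
    "propose_candidates",
    "non_max_suppression",
    "detect",
    "optimize_thresholds",
    "import_external_labels",
]


@dataclass
class DetectionConfig:
    """Detector settings.

    threshold: "otsu" or a fixed intensity value.  score_threshold prunes
    low-confidence candidates before NMS; nms_threshold is the maximum
    allowed pairwise IoU between kept detections; min_volume drops tiny
    rasterized instances.
    """

    rays: RaySet = field(default_factory=lambda: fibonacci_rays(96))
    threshold: str | float = "otsu"
    score_threshold: float = 0.4
    nms_threshold: float = 0.4
    min_volume: int = 30
    march_step: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0, 1]")
        if not 0.0 <= self.nms_threshold <= 1.0:
            raise ValueError("nms_threshold must lie in [0, 1]")
        if self.min_volume < 1:
            raise ValueError("min_volume must be >= 1")


@dataclass
class CandidateSet:
    """Scored star-convex candidates over one source volume."""

    candidates: list[StarConvexInstance]
    shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.candidates)


def _binarize(image: np.ndarray, threshold: str | float) -> np.ndarray:
    if threshold == "otsu":
        if image.max() == image.min():
            return np.zeros(image.shape, dtype=bool)
        return image > threshold_otsu(image)
    return image > float(threshold)


def propose_candidates(image: ImageVolume, cfg: DetectionConfig) -> CandidateSet:
    """Candidate centers from local maxima of the interior distance transform.

    Plateaus of equal distance-transform value are merged: each 26-connected
    plateau contributes one candidate at its most central voxel.  Identical
    centers are deduplicated keeping the maximum score.
    """
    data = np.asarray(image.data, dtype=float)
    fg = _binarize(data, cfg.threshold)
    if not fg.any():
        return CandidateSet([], data.shape)
    dist = ndimage.distance_transform_edt(fg)
    global_max = float(dist.max())
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (dist == ndimage.maximum_filter(dist, footprint=footprint)) & fg
    # Merge 26-connected plateaus into one candidate each.
    plat_labels, n_plat = ndimage.label(local_max, structure=footprint)
    candidates: dict[tuple[int, int, int], StarConvexInstance] = {}
    centroids = ndimage.center_of_mass(local_max, plat_labels, range(1, n_plat + 1))
    for plat_id, centroid in enumerate(centroids, start=1):
        coords = np.round(centroid).astype(int)
        coords = np.clip(coords, 0, np.array(data.shape) - 1)
        center = tuple(int(v) for v in coords)
        if plat_labels[center] != plat_id:
            # Ring-shaped plateau: its centroid falls off the plateau; snap
            # to the plateau voxel nearest the centroid.
            voxels = np.argwhere(plat_labels == plat_id)
            center = tuple(
                int(v) for v in voxels[np.argmin(((voxels - centroid) ** 2).sum(axis=1))]
            )
        score = float(dist[center] / global_max)
        dists = boundary_distances(fg, center, cfg.rays, step=cfg.march_step)
        inst = StarConvexInstance(center=center, dists=dists, score=score)
        prev = candidates.get(center)
        if prev is None or inst.score > prev.score:
            candidates[center] = inst
    cands = sorted(candidates.values(), key=lambda c: (-c.score, c.center))
    return CandidateSet(cands, data.shape)


def _candidate_masks(cands: list[StarConvexInstance], rays: RaySet, shape) -> list[np.ndarray]:
    return [rasterize(c, rays, shape) for c in cands]


def non_max_suppression(
    cands: CandidateSet, rays: RaySet, nms_threshold: float
) -> CandidateSet:
    """Greedy NMS in descending score order (ties by center lexicographic).

    A candidate survives iff its rasterized-polyhedron IoU with every
    already-kept candidate is <= nms_threshold.  Scores are unchanged.
    """
    if not 0.0 <= nms_threshold <= 1.0:
        raise ValueError("nms_threshold must lie in [0, 1]")
    order = sorted(cands.candidates, key=lambda c: (-c.score, c.center))
    kept: list[StarConvexInstance] = []
    kept_masks: list[np.ndarray] = []
    for cand in order:
        mask = rasterize(cand, rays, cands.shape)
        inter_over_union = [
            _pair_iou(mask, km) for km in kept_masks
        ]
        if all(iou <= nms_threshold for iou in inter_over_union):
            kept.append(cand)
            kept_masks.append(mask)
    return CandidateSet(kept, cands.shape)


def _pair_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    if inter == 0:
        return 0.0
    union = np.count_nonzero(a) + np.count_nonzero(b) - inter
    return inter / union


def detect(image: ImageVolume, cfg: DetectionConfig) -> LabelVolume:
    """Full detection: propose, score-filter, NMS, rasterize to labels.

    Labels are 1..k in descending-score order; voxels claimed by several
    rasterized survivors go to the higher-scoring one; instances smaller
    than min_volume are dropped and the remainder relabelled contiguously.
    """
    cands = propose_candidates(image, cfg)
    cands.candidates = [c for c in cands.candidates if c.score >= cfg.score_threshold]
    kept = non_max_suppression(cands, cfg.rays, cfg.nms_threshold)
    labels = np.zeros(cands.shape, dtype=np.int32)
    # Paint lowest score first so higher scores overwrite contested voxels.
    for idx in range(len(kept.candidates) - 1, -1, -1):
        mask = rasterize(kept.candidates[idx], cfg.rays, cands.shape)
        labels[mask] = idx + 1
    # Drop sub-minimum instances, relabel to 1..k preserving score order.
    out = np.zeros_like(labels)
    next_label = 1
    for idx in range(1, len(kept.candidates) + 1):
        voxels = labels == idx
        if np.count_nonzero(voxels) >= cfg.min_volume:
            out[voxels] = next_label
            next_label += 1
    return LabelVolume(out)


def optimize_thresholds(
    candidate_sets: list[CandidateSet],
    gt_volumes: list[LabelVolume],
    cfg: DetectionConfig,
    score_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    nms_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    taus: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
) -> tuple[float, float]:
    """Exhaustive grid search for (score_threshold, nms_threshold).

    Objective: mean F1 over the tau grid, averaged over validation
    volumes.  Ties break toward the smaller nms_threshold, then the
    smaller score_threshold.  Deterministic for fixed inputs.
    """
    from .evaluation import detection_metrics, match_instances

    if not score_grid or not nms_grid:
        raise ValueError("threshold grids must be nonempty")
    if len(candidate_sets) != len(gt_volumes) or not candidate_sets:
        raise ValueError("need matching nonempty candidate and ground-truth lists")
    best = None
    for nms_t in sorted(nms_grid):
        for score_t in sorted(score_grid):
            f1s = []
            for cands, gt in zip(candidate_sets, gt_volumes):
                sub = CandidateSet(
                    [c for c in cands.candidates if c.score >= score_t], cands.shape
                )
                kept = non_max_suppression(sub, cfg.rays, nms_t)
                labels = np.zeros(cands.shape, dtype=np.int32)
                for idx in range(len(kept.candidates) - 1, -1, -1):
                    mask = rasterize(kept.candidates[idx], cfg.rays, cands.shape)
                    labels[mask] = idx + 1
                for tau in taus:
                    m = match_instances(gt.data, labels, tau)
                    f1s.append(detection_metrics(m)[2])
            objective = float(np.mean(f1s))
            if best is None or objective > best[0] + 1e-12:
                best = (objective, score_t, nms_t)
    return best[1], best[2]


def import_external_labels(path) -> LabelVolume:
    """Adapter for label volumes produced by any external segmentation.

    Labels are relabelled to 1..k in order of first appearance (raster
    scan order), so arbitrary label values flow into evaluation,
    measurement and valve sorting unchanged in meaning.
    """
    vol = read_volume(path, as_labels=True)
    data = vol.data
    flat = data.ravel()
    nonzero = flat[flat > 0]
    # Order of first appearance.
    _, first_idx = np.unique(nonzero, return_index=True)
    order = nonzero[np.sort(first_idx)]
    mapping = np.zeros(int(data.max()) + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        mapping[old] = new
    return LabelVolume(mapping[data])
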