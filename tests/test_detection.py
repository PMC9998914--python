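"""Candidate proposal, NMS vs brute force, end-to-end detection, adapter."""

import numpy as np
import pytest
import tifffile

from podstar.detection import (
    CandidateSet,
    DetectionConfig,
    detect,
    import_external_labels,
    non_max_suppression,
    optimize_thresholds,
    propose_candidates,
)
from podstar.evaluation import detection_metrics, match_instances
from podstar.geometry import StarConvexInstance, fibonacci_rays, mask_iou, rasterize
from podstar.io import ImageVolume, LabelVolume


RAYS = fibonacci_rays(32)


def bright_ball_image(centers, radius=8, shape=(48, 48, 48), hi=200.0, lo=20.0):
    img = np.full(shape, lo, dtype=float)
    z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]]
    for c in centers:
        img[(z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= radius**2] = hi
    return ImageVolume(img)


def ball_candidate(center, radius, score, shape):
    return StarConvexInstance(center, np.full(RAYS.n, float(radius)), score)


def reference_greedy_keep(cands, masks, threshold):
    """Independent reimplementation of greedy suppression over explicit
    pairwise IoUs (brute-force voxel counting)."""
    order = sorted(range(len(cands)), key=lambda i: (-cands[i].score, cands[i].center))
    kept = []
    for i in order:
        ok = True
        for j in kept:
            inter = np.count_nonzero(masks[i] & masks[j])
            union = np.count_nonzero(masks[i] | masks[j])
            if union and inter / union > threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    return sorted(cands[i].center for i in kept)


class TestProposeCandidates:
    def test_zero_volume_gives_empty_set(self):
        cfg = DetectionConfig(rays=RAYS, threshold=0.5)
        cands = propose_candidates(ImageVolume(np.zeros((8, 8, 8))), cfg)
        assert len(cands) == 0

    def test_single_ball_center_and_score(self):
        img = bright_ball_image([(24, 24, 24)])
        cfg = DetectionConfig(rays=RAYS, threshold=100.0)
        cands = propose_candidates(img, cfg)
        assert len(cands) >= 1
        best = cands.candidates[0]
        assert np.linalg.norm(np.array(best.center) - 24.0) <= 2.0
        assert best.score == 1.0

    def test_two_disjoint_balls_two_components(self):
        img = bright_ball_image([(14, 14, 14), (34, 34, 34)], radius=7)
        cfg = DetectionConfig(rays=RAYS, threshold=100.0)
        cands = propose_candidates(img, cfg)
        assert len(cands) >= 2
        centers = np.array([c.center for c in cands.candidates[:2]])
        d = np.linalg.norm(centers - np.array([14, 14, 14]), axis=1)
        assert d.min() <= 3 and d.max() >= 20  # one per component


class TestNonMaxSuppression:
    def test_duplicate_candidates_keep_highest_score(self):
        shape = (32, 32, 32)
        a = ball_candidate((16, 16, 16), 6, 0.9, shape)
        b = ball_candidate((16, 16, 16), 6, 0.8, shape)
        kept = non_max_suppression(CandidateSet([a, b], shape), RAYS, 0.4)
        assert [c.score for c in kept.candidates] == [0.9]

    def test_disjoint_candidates_all_kept(self):
        shape = (48, 32, 32)
        a = ball_candidate((10, 16, 16), 5, 0.9, shape)
        b = ball_candidate((36, 16, 16), 5, 0.2, shape)
        kept = non_max_suppression(CandidateSet([a, b], shape), RAYS, 0.0)
        assert len(kept) == 2

    def test_chain_suppression_keeps_ends(self):
        # A-B and B-C overlap heavily, A-C are disjoint; scores A>B>C.
        # B is suppressed by A, C survives because A-C IoU is 0.
        shape = (64, 32, 32)
        a = ball_candidate((20, 16, 16), 7, 0.9, shape)
        b = ball_candidate((24, 16, 16), 7, 0.8, shape)
        c = ball_candidate((44, 16, 16), 5, 0.7, shape)
        kept = non_max_suppression(CandidateSet([a, b, c], shape), RAYS, 0.3)
        assert [k.score for k in kept.candidates] == [0.9, 0.7]

    @pytest.mark.parametrize("threshold", [0.0, 0.2, 0.5])
    def test_agrees_with_brute_force_on_random_sets(self, threshold):
        rng = np.random.default_rng(11)
        shape = (40, 40, 40)
        for _ in range(5):
            n = rng.integers(2, 7)
            cands = [
                ball_candidate(
                    tuple(rng.integers(8, 32, size=3)),
                    rng.integers(4, 9),
                    float(rng.uniform(0.1, 1.0)),
                    shape,
                )
                for _ in range(n)
            ]
            masks = [rasterize(c, RAYS, shape) for c in cands]
            kept = non_max_suppression(CandidateSet(cands, shape), RAYS, threshold)
            assert sorted(c.center for c in kept.candidates) == reference_greedy_keep(
                cands, masks, threshold
            )

    def test_kept_pairwise_iou_bounded(self):
        rng = np.random.default_rng(3)
        shape = (40, 40, 40)
        cands = [
            ball_candidate(tuple(rng.integers(10, 30, size=3)), 7, float(s), shape)
            for s in rng.uniform(0.2, 1.0, size=6)
        ]
        kept = non_max_suppression(CandidateSet(cands, shape), RAYS, 0.3)
        masks = [rasterize(c, RAYS, shape) for c in kept.candidates]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert mask_iou(masks[i], masks[j]) <= 0.3 + 1e-12


class TestDetect:
    def test_all_zero_image_gives_empty_labels(self):
        cfg = DetectionConfig(rays=RAYS, threshold=0.5)
        out = detect(ImageVolume(np.zeros((8, 8, 8))), cfg)
        assert len(out.ids()) == 0

    def test_well_separated_balls_detected_exactly(self):
        img = bright_ball_image([(12, 24, 24), (36, 24, 24)], radius=8)
        cfg = DetectionConfig(rays=RAYS, threshold=100.0, score_threshold=0.4)
        out = detect(img, cfg)
        assert len(out.ids()) == 2
        gt = np.zeros(img.data.shape, dtype=np.int32)
        z, y, x = np.mgrid[:48, :48, :48]
        gt[(z - 12) ** 2 + (y - 24) ** 2 + (x - 24) ** 2 <= 64] = 1
        gt[(z - 36) ** 2 + (y - 24) ** 2 + (x - 24) ** 2 <= 64] = 2
        m = match_instances(gt, out.data, 0.5)
        assert detection_metrics(m)[2] == 1.0

    def test_saturated_score_threshold(self):
        img = bright_ball_image([(24, 24, 24)])
        cfg = DetectionConfig(rays=RAYS, threshold=100.0, score_threshold=1.0)
        out = detect(img, cfg)
        assert len(out.ids()) <= 1  # only the perfect-score candidate may survive

    def test_label_count_bounded_by_candidates(self, small_pod):
        pod_cfg, image, _, _ = small_pod
        threshold = 0.5 * (pod_cfg.intensity_wall + pod_cfg.intensity_seed)
        cfg = DetectionConfig(rays=RAYS, threshold=threshold)
        cands = propose_candidates(image, cfg)
        out = detect(image, cfg)
        assert len(out.ids()) <= len(cands)


class TestOptimizeThresholds:
    def test_duplicate_candidates_need_nms(self):
        shape = (48, 32, 32)
        gt = np.zeros(shape, dtype=np.int32)
        z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]]
        gt[(z - 14) ** 2 + (y - 16) ** 2 + (x - 16) ** 2 <= 36] = 1
        gt[(z - 34) ** 2 + (y - 16) ** 2 + (x - 16) ** 2 <= 36] = 2
        cands = CandidateSet(
            [
                ball_candidate((14, 16, 16), 6, 1.0, shape),
                ball_candidate((15, 16, 16), 6, 0.9, shape),  # injected duplicate
                ball_candidate((34, 16, 16), 6, 0.95, shape),
            ],
            shape,
        )
        cfg = DetectionConfig(rays=RAYS)
        score_t, nms_t = optimize_thresholds([cands], [LabelVolume(gt)], cfg)
        assert nms_t < 1.0  # pruning the duplicate beats keeping it
        # Reproducible: same inputs, same output.
        assert (score_t, nms_t) == optimize_thresholds([cands], [LabelVolume(gt)], cfg)

    def test_empty_grid_raises(self):
        cfg = DetectionConfig(rays=RAYS)
        with pytest.raises(ValueError):
            optimize_thresholds([], [], cfg)


class TestImportExternalLabels:
    def test_relabels_in_order_of_first_appearance(self, tmp_path):
        data = np.zeros((3, 4, 4), dtype=np.int32)
        data[0, 0, 0] = 7
        data[2, 1:3, 1:3] = 3
        path = tmp_path / "ext.tif"
        tifffile.imwrite(path, data)
        out = import_external_labels(path)
        assert out.data[0, 0, 0] == 1
        assert out.data[2, 1, 1] == 2

    def test_identity_on_contiguous_labels(self, tmp_path, small_pod):
        _, _, labels, _ = small_pod
        path = tmp_path / "gt.tif"
        tifffile.imwrite(path, labels.data)
        out = import_external_labels(path)
        np.testing.assert_array_equal(out.data, labels.data)

    def test_empty_volume(self, tmp_path):
        path = tmp_path / "empty.tif"
        tifffile.imwrite(path, np.zeros((2, 3, 3), dtype=np.uint16))
        out = import_external_labels(path)
        assert len(out.ids()) == 0
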