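"""Detector behaviour and the IoU/AP evaluation contract."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rodmorph.detection import (
    BBox,
    Detection,
    average_precision,
    detect_cells,
    evaluate_detections,
    iou,
    match_greedy,
)
from rodmorph.synthgen import CONTROL_PRESET, generate_scene, render_capsule


# ---------------------------------------------------------------- brute force
def brute_force_eval(dets, gts, threshold):
    """Naive reference: explicit loops, no shared code with the package.

    Matching: walk detections from highest score; scan every truth, keep
    the unmatched one with the largest IoU >= threshold.  AP: recompute
    precision from scratch at each rank and integrate the running-max
    envelope over recall increments.
    """
    def naive_iou(a, b):
        w = min(a[2], b[2]) - max(a[0], b[0])
        h = min(a[3], b[3]) - max(a[1], b[1])
        if w <= 0 or h <= 0:
            return 0.0
        i = w * h
        aa = (a[2] - a[0]) * (a[3] - a[1])
        bb = (b[2] - b[0]) * (b[3] - b[1])
        return i / (aa + bb - i)

    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    used = set()
    flags = []
    for i in order:
        cand = None
        cand_iou = None
        for j in range(len(gts)):
            if j in used:
                continue
            v = naive_iou(dets[i][0], gts[j])
            if v >= threshold and (cand_iou is None or v > cand_iou):
                cand, cand_iou = j, v
        if cand is None:
            flags.append(False)
        else:
            used.add(cand)
            flags.append(True)
    if not gts:
        return 0.0
    # naive all-points AP
    ap = 0.0
    prev_recall = 0.0
    for k in range(len(flags)):
        tp = sum(flags[:k + 1])
        recall = tp / len(gts)
        if recall > prev_recall:
            # best precision at any rank with recall >= this one
            best = 0.0
            for m in range(k, len(flags)):
                best = max(best, sum(flags[:m + 1]) / (m + 1))
            ap += (recall - prev_recall) * best
            prev_recall = recall
    return ap


# ------------------------------------------------------------------------ iou
class TestIoU:
    def test_identical_boxes(self):
        b = BBox(2, 3, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BBox(0, 0, 5, 5), BBox(10, 10, 20, 20)) == 0.0

    def test_half_overlap_worked_example(self):
        assert iou(BBox(0, 0, 10, 10), BBox(5, 0, 15, 10)) == pytest.approx(1 / 3)

    @given(st.tuples(*[st.integers(0, 40) for _ in range(4)]),
           st.tuples(*[st.integers(0, 40) for _ in range(4)]))
    def test_symmetry(self, a, b):
        try:
            ba = BBox(a[0], a[1], a[0] + a[2] + 1, a[1] + a[3] + 1)
            bb = BBox(b[0], b[1], b[0] + b[2] + 1, b[1] + b[3] + 1)
        except ValueError:
            return
        assert iou(ba, bb) == pytest.approx(iou(bb, ba))

    def test_monotone_under_translation(self):
        a = BBox(0, 0, 10, 10)
        vals = [iou(a, BBox(dx, 0, dx + 10, 10)) for dx in range(0, 15)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))


# ------------------------------------------------------------------- detector
class TestDetectCells:
    def test_blank_image_yields_nothing(self):
        assert detect_cells(np.full((128, 128), 80, np.uint8)) == []

    def test_rejects_color_image(self):
        with pytest.raises(ValueError):
            detect_cells(np.zeros((10, 10, 3), np.uint8))

    def test_single_capsule_found_with_high_iou(self):
        mask = render_capsule(60, 20, 30, (100, 100), (200, 200))
        img = np.where(mask, 160, 60).astype(np.uint8)
        dets = detect_cells(img)
        assert len(dets) == 1
        ys, xs = np.nonzero(mask)
        truth = BBox(xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
        assert iou(dets[0].box, truth) >= 0.90

    def test_two_separated_capsules(self):
        m1 = render_capsule(60, 20, 0, (70, 60), (300, 300))
        m2 = render_capsule(50, 22, 90, (200, 220), (300, 300))
        img = np.where(m1 | m2, 160, 60).astype(np.uint8)
        dets = detect_cells(img)
        assert len(dets) == 2
        for m in (m1, m2):
            ys, xs = np.nonzero(m)
            truth = BBox(xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
            assert max(iou(d.box, truth) for d in dets) >= 0.85

    def test_perfect_ap_on_clean_scene(self):
        # noiseless, no clipping, no overlap -> the detector is exact enough
        # for AP50 = 1.0 against the ground-truth boxes
        cfg = dataclasses.replace(CONTROL_PRESET, n_cells=5,
                                  canvas_size=(420, 420), border_margin=10,
                                  min_separation=8, noise_sigma=0.0, seed=2)
        scene = generate_scene(cfg)
        dets = detect_cells(scene.image)
        gts = []
        for m in scene.masks:
            ys, xs = np.nonzero(m)
            gts.append(BBox(xs.min(), ys.min(), xs.max() + 1, ys.max() + 1))
        res = evaluate_detections({"s": dets}, {"s": gts})
        assert res.ap50 == 1.0


# ----------------------------------------------------------------- evaluation
class TestEvaluateDetections:
    def test_perfect_detections(self):
        gts = [BBox(0, 0, 10, 10), BBox(30, 30, 50, 40)]
        dets = [Detection(b, 1.0) for b in gts]
        res = evaluate_detections({"i": dets}, {"i": gts})
        assert res.ap50 == 1.0
        assert res.map_50_95 == 1.0

    def test_no_detections(self):
        res = evaluate_detections({"i": []}, {"i": [BBox(0, 0, 10, 10)]})
        assert res.ap50 == 0.0 and res.map_50_95 == 0.0

    def test_empty_ground_truth_defines_ap_zero(self):
        res = evaluate_detections({"i": [Detection(BBox(0, 0, 5, 5), 0.9)]},
                                  {"i": []})
        assert res.ap50 == 0.0

    def test_worked_two_truth_three_detection_example(self):
        # ranked [TP(0.9), FP(0.8), TP(0.7)] at IoU 0.5:
        # AP = 0.5*1 + 0.5*(2/3) = 0.8333
        gts = [BBox(0, 0, 10, 10), BBox(40, 40, 50, 50)]
        dets = [Detection(BBox(0, 0, 10, 10), 0.9),
                Detection(BBox(100, 100, 110, 110), 0.8),
                Detection(BBox(40, 40, 50, 50), 0.7)]
        res = evaluate_detections({"i": dets}, {"i": gts}, thresholds=(0.5,))
        assert res.ap50 == pytest.approx(0.5 * 1 + 0.5 * (2 / 3), abs=1e-9)

    def test_map_is_mean_of_thresholds(self):
        gts = [BBox(0, 0, 10, 10)]
        dets = [Detection(BBox(0, 1, 10, 11), 0.9)]  # IoU = 9/11 ~ 0.818
        res = evaluate_detections({"i": dets}, {"i": gts})
        assert res.map_50_95 == pytest.approx(
            np.mean(list(res.ap_per_threshold.values())))

    def test_matches_brute_force_on_small_scenes(self):
        """Property sweep: exact agreement with the naive matcher, <= 5 boxes."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            n_gt = int(rng.integers(0, 6))
            n_det = int(rng.integers(0, 6))
            gts, dets = [], []
            for _ in range(n_gt):
                x, y = rng.integers(0, 60, 2)
                w, h = rng.integers(5, 25, 2)
                gts.append(BBox(x, y, x + w, y + h))
            for _ in range(n_det):
                x, y = rng.integers(0, 60, 2)
                w, h = rng.integers(5, 25, 2)
                dets.append(Detection(BBox(x, y, x + w, y + h),
                                      float(rng.uniform(0, 1))))
            for thr in (0.3, 0.5, 0.75):
                res = evaluate_detections({"i": dets}, {"i": gts},
                                          thresholds=(thr,))
                ref = brute_force_eval(
                    [((d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max),
                      d.score) for d in dets],
                    [(g.x_min, g.y_min, g.x_max, g.y_max) for g in gts], thr)
                assert res.ap_per_threshold[thr] == pytest.approx(ref, abs=1e-9)
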