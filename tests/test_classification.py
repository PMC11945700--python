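"""Tiling, crop-validity labelling, filtering and confusion arithmetic."""

import dataclasses

import numpy as np
import pytest

from rodmorph.classification import (
    ConfusionMatrix2x2,
    Crop,
    CropLabel,
    GeometricOracle,
    LogisticCropClassifier,
    accuracy_from_confusion,
    condition_from_tile_lengths,
    crops_from_scene,
    filter_crops,
    label_crop_geometric,
    tile_image,
)
from rodmorph.detection import BBox
from rodmorph.synthgen import CONTROL_PRESET, generate_scene


class TestTileImage:
    @pytest.mark.parametrize("shape,expected", [
        ((1000, 1500), 24),   # the 1500x1000 field -> 6x4 grid
        ((250, 250), 1),
        ((500, 600), 4),      # 100-px remainder column dropped
    ])
    def test_grid_counts(self, shape, expected):
        img = np.zeros(shape, np.uint8)
        assert len(tile_image(img)) == expected

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((100, 300), np.uint8))

    def test_reassembly_is_lossless(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (520, 770), dtype=np.uint8)
        tiles = tile_image(img)
        rebuilt = np.zeros((500, 750), np.uint8)
        for t in tiles:
            r, c = t.grid_position
            rebuilt[r * 250:(r + 1) * 250, c * 250:(c + 1) * 250] = t.pixels
        assert np.array_equal(rebuilt, img[:500, :750])


class TestConfusionArithmetic:
    def test_printed_confusion_matrix(self):
        m = ConfusionMatrix2x2(tp=2182, fn=18, fp=116, tn=2084)
        assert accuracy_from_confusion(m) == pytest.approx(4266 / 4400)
        assert round(accuracy_from_confusion(m), 2) == 0.97

    def test_all_correct(self):
        assert accuracy_from_confusion(ConfusionMatrix2x2(10, 0, 0, 10)) == 1.0

    def test_coin_flip(self):
        assert accuracy_from_confusion(ConfusionMatrix2x2(50, 50, 50, 50)) == 0.5

    def test_invariant_under_class_transpose(self):
        m = ConfusionMatrix2x2(2182, 18, 116, 2084)
        swapped = ConfusionMatrix2x2(tp=m.tn, fn=m.fp, fp=m.fn, tn=m.tp)
        assert accuracy_from_confusion(m) == accuracy_from_confusion(swapped)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_from_confusion(ConfusionMatrix2x2(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix2x2(-1, 0, 0, 1)


class TestCropLabelInvariant:
    def test_reason_none_iff_representative(self):
        with pytest.raises(ValueError):
            CropLabel("representative", "border")
        with pytest.raises(ValueError):
            CropLabel("non_representative", "none")


class TestGeometricLabeler:
    def test_mixed_scene_labels(self, mixed_scene):
        oracle = GeometricOracle(mixed_scene)
        for crop in crops_from_scene(mixed_scene):
            cell = next(c for c in mixed_scene.cells if c.id == crop.cell_id)
            lab = oracle(crop)
            if cell.category == "single":
                assert lab.label == "representative"
            else:
                assert lab.label == "non_representative"

    def test_border_cell_flagged(self, mixed_scene):
        border = [c for c in mixed_scene.cells if c.category == "border_clipped"]
        for cell in border:
            idx = [c.id for c in mixed_scene.cells].index(cell.id)
            ys, xs = np.nonzero(mixed_scene.masks[idx])
            box = BBox(float(xs.min()), float(ys.min()),
                       float(xs.max()) + 1, float(ys.max()) + 1)
            lab = label_crop_geometric(cell, box, mixed_scene)
            assert (lab.label, lab.reason) == ("non_representative", "border")

    def test_truncating_box_flags_single(self, mixed_scene):
        # shrink a single's box so part of its mask falls outside
        single = next(c for c in mixed_scene.cells if c.category == "single")
        idx = [c.id for c in mixed_scene.cells].index(single.id)
        ys, xs = np.nonzero(mixed_scene.masks[idx])
        box = BBox(float(xs.min()) + 6, float(ys.min()),
                   float(xs.max()) + 1, float(ys.max()) + 1)
        lab = label_crop_geometric(single, box, mixed_scene)
        assert lab.label == "non_representative"

    def test_purity_on_synthetic_scenes(self, mixed_scene):
        """The oracle has precision = recall = 1 against generator labels."""
        crops = crops_from_scene(mixed_scene)
        kept, log = filter_crops(crops, GeometricOracle(mixed_scene))
        truth_repr = {c.id for c in mixed_scene.cells if c.category == "single"}
        assert {c.cell_id for c in kept} == truth_repr
        assert len(kept) + len(log) == len(crops)


class TestFilterCrops:
    def _crop(self, k):
        return Crop(k, np.zeros((8, 8), np.uint8), BBox(0, 0, 8, 8))

    def test_all_representative_is_identity(self):
        crops = [self._crop(i) for i in range(4)]
        kept, log = filter_crops(
            crops, lambda c: CropLabel("representative", "none"))
        assert kept == crops and log == []

    def test_counts_by_category(self):
        labels = (["representative"] * 10 + ["border"] * 5 + ["fission"] * 5)

        def clf(c):
            lab = labels[c.crop_id]
            if lab == "representative":
                return CropLabel("representative", "none")
            return CropLabel("non_representative", lab)

        crops = [self._crop(i) for i in range(20)]
        kept, log = filter_crops(crops, clf)
        assert len(kept) == 10 and len(log) == 10
        assert sum(r["reason"] == "border" for r in log) == 5
        assert sum(r["reason"] == "fission" for r in log) == 5

    def test_classifier_failure_rejects_and_continues(self):
        def clf(c):
            if c.crop_id == 1:
                raise RuntimeError("boom")
            return CropLabel("representative", "none")

        crops = [self._crop(i) for i in range(3)]
        kept, log = filter_crops(crops, clf)
        assert [c.crop_id for c in kept] == [0, 2]
        assert log[0]["crop_id"] == 1 and "boom" in log[0]["error"]


class TestLogisticBackend:
    def test_heldout_accuracy_on_synthetic_crops(self):
        """Train on ~840 synthetic crops, test on a held-out ~120."""
        crops, labels = [], []
        seed = 100
        while len(crops) < 960:
            cfg = dataclasses.replace(
                CONTROL_PRESET, n_cells=10, canvas_size=(384, 384),
                fraction_fission=0.35, seed=seed)
            seed += 1
            scene = generate_scene(cfg)
            oracle = GeometricOracle(scene)
            for crop in crops_from_scene(scene):
                crops.append(crop)
                labels.append(oracle(crop).label)
        crops, labels = crops[:960], labels[:960]
        clf = LogisticCropClassifier(random_state=0).fit(crops[:840], labels[:840])
        correct = sum(clf(c).label == l for c, l in zip(crops[840:], labels[840:]))
        assert correct / 120 >= 0.85

    def test_unfitted_raises(self):
        clf = LogisticCropClassifier()
        with pytest.raises(RuntimeError):
            clf(Crop(0, np.zeros((8, 8), np.uint8), BBox(0, 0, 8, 8)))


class TestConditionRule:
    def test_threshold_separates_condition_medians(self):
        assert condition_from_tile_lengths(53.0) == "control"
        assert condition_from_tile_lengths(75.0) == "acidic"
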