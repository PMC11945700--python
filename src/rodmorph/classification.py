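"""Tile-level condition discrimination and crop-validity filtering.

Two classification tasks sit in the pipeline.  First, whole micrographs are
cut into 250x250 tiles and each tile is assigned a growth condition
(control vs acidic); here the deterministic baseline classifies a tile by
the median length of the cells detected in it, since acid stress lengthens
the cells.  Second — the filtering step of the measurement pipeline — every
detected crop is labelled ``representative`` (its box dimensions reflect
the true cell dimensions) or ``non_representative`` (clipped by the border,
overlapped by a neighbour, mid-fission, or part of a filament), and only
representative crops are measured.

Both tasks sit behind a plug-in contract: any callable mapping a crop to a
``(label, confidence)`` pair can replace the built-in backends, so a
fine-tuned CNN can be dropped in without touching the pipeline.  The
backends shipped here are the geometric oracle (exact, needs synthetic
ground truth) and a logistic-regression model on shape features (trainable
from synthetic crops, no ground truth at inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

import numpy as np

from .detection import BBox
from .synthgen import SINGLE, CellGT, Scene, export_annotations

__all__ = [
    "Tile",
    "Crop",
    "CropLabel",
    "ConfusionMatrix2x2",
    "tile_image",
    "label_crop_geometric",
    "filter_crops",
    "accuracy_from_confusion",
    "GeometricOracle",
    "LogisticCropClassifier",
    "crop_features",
    "condition_from_tile_lengths",
    "crops_from_scene",
]

REPRESENTATIVE = "representative"
NON_REPRESENTATIVE = "non_representative"
REASONS = ("none", "border", "overlap", "fission", "filament_partial")

# Padding added around a box before cropping, so edges at the cell boundary
# survive later edge detection.
CROP_PAD = 2


@dataclass(frozen=True)
class Tile:
    pixels: np.ndarray
    source_image: str
    grid_position: tuple[int, int]  # (row, col)


@dataclass(frozen=True)
class CropLabel:
    label: str
    reason: str = "none"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in (REPRESENTATIVE, NON_REPRESENTATIVE):
            raise ValueError(f"unknown label {self.label!r}")
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if (self.reason == "none") != (self.label == REPRESENTATIVE):
            raise ValueError("reason must be 'none' iff label is representative")


@dataclass(frozen=True)
class Crop:
    """One detected cell crop: the padded pixel window plus its box."""

    crop_id: int
    pixels: np.ndarray
    box: BBox
    source_image: str = ""
    cell_id: Optional[int] = None  # ground-truth link, synthetic scenes only


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts with rows = actual class, cols = predicted class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def accuracy_from_confusion(m: ConfusionMatrix2x2) -> float:
    """Proportion of correct predictions, (tp + tn) / total."""
    if m.total == 0:
        raise ValueError("confusion matrix is empty")
    return (m.tp + m.tn) / m.total


def tile_image(image: np.ndarray, tile_size: int = 250,
               source_image: str = "") -> list[Tile]:
    """Cut an image into a non-overlapping row-major grid of square tiles.

    Partial edge tiles are dropped, so a 1500x1000 image yields 6*4 = 24
    tiles of 250x250.
    """
    H, W = image.shape[:2]
    if H < tile_size or W < tile_size:
        raise ValueError(
            f"image {H}x{W} smaller than one {tile_size}x{tile_size} tile")
    tiles = []
    for r in range(H // tile_size):
        for c in range(W // tile_size):
            px = image[r * tile_size:(r + 1) * tile_size,
                       c * tile_size:(c + 1) * tile_size]
            tiles.append(Tile(px, source_image, (r, c)))
    return tiles


def label_crop_geometric(cell: CellGT, box: BBox, scene: Scene) -> CropLabel:
    """Exact validity label from synthetic ground truth.

    Representative iff the cell is a single, its full mask lies inside the
    box, and no foreign mask intrudes into the box beyond the scene's
    overlap allowance.
    """
    idx = next(i for i, c in enumerate(scene.cells) if c.id == cell.id)
    mask = scene.masks[idx]
    if cell.category != SINGLE:
        reason = {"fission_pair_member": "fission", "filament": "filament_partial",
                  "border_clipped": "border", "overlapping": "overlap"}[cell.category]
        return CropLabel(NON_REPRESENTATIVE, reason, 1.0)
    x0, y0 = int(np.floor(box.x_min)), int(np.floor(box.y_min))
    x1, y1 = int(np.ceil(box.x_max)), int(np.ceil(box.y_max))
    inside = np.zeros_like(mask)
    inside[max(0, y0):y1, max(0, x0):x1] = True
    if np.logical_and(mask, ~inside).any():
        return CropLabel(NON_REPRESENTATIVE, "border", 1.0)
    allowance = scene.config.overlap_allowance * mask.sum()
    for j, other in enumerate(scene.masks):
        if j == idx:
            continue
        if np.logical_and(other, inside).sum() > allowance:
            return CropLabel(NON_REPRESENTATIVE, "overlap", 1.0)
    return CropLabel(REPRESENTATIVE, "none", 1.0)


class CropClassifier(Protocol):
    """Plug-in contract: crop in, (label, confidence) out."""

    def __call__(self, crop: Crop) -> CropLabel: ...


def filter_crops(
    crops: list[Crop], classifier: Callable[[Crop], CropLabel]
) -> tuple[list[Crop], list[dict]]:
    """Keep representative crops; log every rejection.

    A classifier failure on a crop rejects that crop (reason recorded) and
    the pipeline continues.  Output order is preserved.
    """
    kept: list[Crop] = []
    log: list[dict] = []
    for crop in crops:
        try:
            lab = classifier(crop)
        except Exception as exc:  # classifier failure is survivable
            log.append({"crop_id": crop.crop_id, "label": NON_REPRESENTATIVE,
                        "reason": "overlap", "confidence": 0.0,
                        "error": str(exc)})
            continue
        if lab.label == REPRESENTATIVE:
            kept.append(crop)
        else:
            log.append({"crop_id": crop.crop_id, "label": lab.label,
                        "reason": lab.reason, "confidence": lab.confidence})
    return kept, log


@dataclass
class GeometricOracle:
    """Classifier backend that answers from synthetic ground truth."""

    scene: Scene
    _by_id: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {c.id: c for c in self.scene.cells}

    def __call__(self, crop: Crop) -> CropLabel:
        if crop.cell_id is None or crop.cell_id not in self._by_id:
            raise ValueError(f"crop {crop.crop_id} has no ground-truth cell")
        return label_crop_geometric(self._by_id[crop.cell_id], crop.box, self.scene)


def crop_features(crop: Crop) -> np.ndarray:
    """Shape features of a crop for the logistic backend.

    Aspect ratio of the box, foreground fill fraction, border contact of
    the foreground with each crop edge, and a coarse 4-bin edge-density
    profile along the crop's long axis (fission septa and filament joints
    show up as interior density dips/spikes).
    """
    from skimage.feature import canny
    from skimage.filters import threshold_otsu

    px = crop.pixels.astype(float)
    h, w = px.shape
    long_side = max(crop.box.x_max - crop.box.x_min,
                    crop.box.y_max - crop.box.y_min)
    short_side = min(crop.box.x_max - crop.box.x_min,
                     crop.box.y_max - crop.box.y_min)
    aspect = long_side / max(short_side, 1.0)
    if np.ptp(px) < 1e-9:
        fg = np.zeros_like(px, dtype=bool)
    else:
        fg = px > threshold_otsu(px)
    fill = fg.mean()
    contact = np.array([fg[0].mean(), fg[-1].mean(), fg[:, 0].mean(),
                        fg[:, -1].mean()])
    edges = canny(px / 255.0, sigma=1.5) if np.ptp(px) > 1e-9 else fg
    axis = 1 if w >= h else 0
    n = px.shape[axis]
    dens = []
    for k in range(4):
        sl = slice(k * n // 4, (k + 1) * n // 4)
        seg = edges[:, sl] if axis == 1 else edges[sl, :]
        dens.append(seg.mean())
    return np.array([aspect, fill, *contact, *dens])


@dataclass
class LogisticCropClassifier:
    """Logistic regression on shape features; trainable from labelled crops."""

    random_state: int = 0
    _model: object = field(default=None, init=False, repr=False)

    def fit(self, crops: list[Crop], labels: list[str]) -> "LogisticCropClassifier":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        X = np.stack([crop_features(c) for c in crops])
        y = np.array([1 if l == REPRESENTATIVE else 0 for l in labels])
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=self.random_state),
        ).fit(X, y)
        return self

    def __call__(self, crop: Crop) -> CropLabel:
        if self._model is None:
            raise RuntimeError("LogisticCropClassifier is not fitted")
        p = float(self._model.predict_proba(crop_features(crop)[None, :])[0, 1])
        if p >= 0.5:
            return CropLabel(REPRESENTATIVE, "none", p)
        # feature model cannot name the cause; report the generic reason
        return CropLabel(NON_REPRESENTATIVE, "overlap", 1.0 - p)


def crops_from_scene(scene: Scene, pad: int = CROP_PAD) -> list[Crop]:
    """All ground-truth cells of a scene as padded crops (oracle-linked)."""
    H, W = scene.image.shape
    out = []
    _, validity = export_annotations(scene)
    for cell, mask in zip(scene.cells, scene.masks):
        ys, xs = np.nonzero(mask)
        box = BBox(float(xs.min()), float(ys.min()),
                   float(xs.max()) + 1, float(ys.max()) + 1)
        x0, y0 = max(0, int(box.x_min) - pad), max(0, int(box.y_min) - pad)
        x1, y1 = min(W, int(box.x_max) + pad), min(H, int(box.y_max) + pad)
        out.append(Crop(crop_id=cell.id, pixels=scene.image[y0:y1, x0:x1],
                        box=box, cell_id=cell.id))
    return out


def condition_from_tile_lengths(median_length_px: float,
                                threshold_px: float = 64.0) -> str:
    """Classify a tile's condition from the median detected cell length.

    The default threshold is the midpoint of the control (53 px) and acidic
    (75 px) median lengths.
    """
    return "acidic" if median_length_px > threshold_px else "control"
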