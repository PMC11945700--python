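"""Cell localization and detector evaluation.

The detection stage turns a grayscale micrograph into scored bounding
boxes, one per candidate cell.  The default detector is classical —
background flattening, Otsu thresholding, morphological opening, connected
components with area/solidity filters — and any learned detector can be
plugged in through the same ``detect_cells`` signature (boxes + scores is
the whole contract).  Evaluation follows the standard average-precision
protocol: greedy score-ordered matching at each IoU threshold, all-points
precision–recall integration, and mAP as the mean of AP over thresholds
0.50:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BBox",
    "Detection",
    "DetectorParams",
    "DetectionEvalResult",
    "iou",
    "detect_cells",
    "evaluate_detections",
    "match_greedy",
    "average_precision",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def clipped(self, height: int, width: int) -> "BBox":
        return BBox(max(0.0, self.x_min), max(0.0, self.y_min),
                    min(float(width), self.x_max), min(float(height), self.y_max))


@dataclass(frozen=True)
class Detection:
    box: BBox
    score: float
    source_image: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass(frozen=True)
class DetectorParams:
    """Knobs of the classical detector.

    ``min_area`` and ``max_area`` bound component size in px²;
    ``min_solidity`` rejects ragged noise blobs; ``opening_radius`` is the
    disc radius of the morphological opening (≈ width/4 of expected cells).
    """

    opening_radius: int = 5
    min_area: float = 120.0
    max_area: float = 1e6
    min_solidity: float = 0.5


@dataclass(frozen=True)
class DetectionEvalResult:
    ap_per_threshold: dict[float, float] = field(default_factory=dict)
    map_50_95: float = 0.0
    ap50: float = 0.0


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes under the half-open convention."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def detect_cells(image: np.ndarray, params: DetectorParams = DetectorParams(),
                 source_image: str = "") -> list[Detection]:
    """Detect candidate cells as scored boxes, sorted by descending score.

    Pipeline: median background subtraction → Otsu threshold → opening
    (disc) → connected components → area and solidity filters.  The score
    is the component solidity, a cheap proxy for how capsule-like the blob
    is.  Deterministic for fixed input and params.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops
    from skimage.morphology import disk, opening

    if image.ndim != 2:
        raise ValueError("detect_cells expects a 2-D grayscale image")
    if image.size == 0:
        raise ValueError("empty image")
    img = image.astype(float)
    flat = img - np.median(img)
    if np.ptp(flat) < 1e-9:
        return []  # blank image, nothing to threshold
    thr = threshold_otsu(flat)
    fg = flat > thr
    # Otsu on a nearly-blank image splits noise; require meaningful contrast.
    if flat[fg].mean() - flat[~fg].mean() < 4 * max(flat[~fg].std(), 1e-9):
        return []
    if params.opening_radius > 0:
        fg = opening(fg, disk(params.opening_radius))
    out: list[Detection] = []
    for rp in regionprops(label(fg)):
        if not (params.min_area <= rp.area <= params.max_area):
            continue
        if rp.solidity < params.min_solidity:
            continue
        y0, x0, y1, x1 = rp.bbox  # skimage: half-open (min_row, min_col, max_row, max_col)
        out.append(Detection(BBox(float(x0), float(y0), float(x1), float(y1)),
                             score=float(min(rp.solidity, 1.0)),
                             source_image=source_image))
    out.sort(key=lambda d: -d.score)
    return out


def match_greedy(
    detections: list[Detection],
    truths: list[BBox],
    threshold: float,
) -> list[bool]:
    """Label each detection TP/FP at one IoU threshold (single image).

    Detections are taken in descending score order (stable in input order
    on ties); each claims the highest-IoU unmatched truth with IoU >= the
    threshold.  Returns TP flags aligned with the score-sorted order.
    """
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    matched = [False] * len(truths)
    flags = []
    for i in order:
        best_j, best_iou = -1, threshold
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = iou(detections[i].box, t)
            if v >= best_iou and v > 0:
                if v > best_iou or best_j == -1:
                    best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def average_precision(tp_flags: list[bool], scores: list[float],
                      n_truth: int) -> float:
    """All-points AP from pooled TP/FP flags ranked by score.

    The precision envelope (running maximum from the right) is integrated
    over the exact recall steps — the continuous interpolation convention.
    """
    if n_truth == 0:
        return 0.0
    if not tp_flags:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_truth
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope, then sum precision at each recall increment
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def evaluate_detections(
    detections_by_image: dict[str, list[Detection]],
    truths_by_image: dict[str, list[BBox]],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> DetectionEvalResult:
    """AP at each IoU threshold plus mAP over 0.50:0.05:0.95.

    Matching is greedy per image; precision–recall is pooled over images
    and integrated with the all-points convention.  With empty ground truth
    AP is defined as 0 at every threshold.
    """
    images = set(detections_by_image) | set(truths_by_image)
    n_truth = sum(len(truths_by_image.get(im, [])) for im in images)
    ap_per: dict[float, float] = {}
    for thr in thresholds:
        flags: list[bool] = []
        scores: list[float] = []
        for im in images:
            dets = detections_by_image.get(im, [])
            gts = truths_by_image.get(im, [])
            f = match_greedy(dets, gts, thr)
            order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
            flags.extend(f)
            scores.extend(dets[i].score for i in order)
        ap_per[float(thr)] = average_precision(flags, scores, n_truth)
    vals = list(ap_per.values())
    return DetectionEvalResult(
        ap_per_threshold=ap_per,
        map_50_95=float(np.mean(vals)) if vals else 0.0,
        ap50=ap_per.get(0.5, 0.0),
    )
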