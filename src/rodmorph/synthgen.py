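"""Synthetic SEM-like scenes of capsule-shaped (spherocylindrical) cells.

Rod-shaped bacteria project onto a 2-D micrograph as capsules: a rectangle
of length ``length - width`` capped by two hemispheres of diameter
``width``.  This module renders such capsules onto a grayscale canvas with
exact per-cell ground truth, including the scene features that make
automated measurement hard in real micrographs: cells caught mid binary
fission (two collinear rods separated by a thin septum gap), filamentous
unseparated chains, cells clipped by the image border, and overlapping
neighbours.  The ground truth produced here is the oracle against which the
detection, filtering and measurement stages are tested.

Coordinates are 0-based, x rightward, y downward; bounding boxes are
half-open ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "CellGT",
    "SceneConfig",
    "Scene",
    "LogNormalSpec",
    "render_capsule",
    "generate_scene",
    "export_annotations",
    "CONTROL_PRESET",
    "ACIDIC_PRESET",
]

# Cell categories
SINGLE = "single"
FISSION = "fission_pair_member"
FILAMENT = "filament"
BORDER = "border_clipped"
OVERLAP = "overlapping"

CATEGORIES = (SINGLE, FISSION, FILAMENT, BORDER, OVERLAP)


@dataclass(frozen=True)
class CellGT:
    """Ground-truth geometry and label for one rendered cell."""

    id: int
    center: tuple[float, float]  # (x, y) pixels
    angle: float                 # degrees in [0, 180)
    length: float                # end-to-end including hemispherical caps, px
    width: float                 # diameter, px
    category: str

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"cell {self.id}: need length >= width > 0, "
                f"got length={self.length}, width={self.width}"
            )
        if not (0.0 <= self.angle < 180.0):
            raise ValueError(f"cell {self.id}: angle must lie in [0, 180)")
        if self.category not in CATEGORIES:
            raise ValueError(f"cell {self.id}: unknown category {self.category!r}")


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal dimension distribution parameterised by median and SD.

    For a log-normal variable, median = exp(mu) and the variance has the
    closed form (e^{sigma^2} - 1) e^{2 mu + sigma^2}; given a target median
    m and SD s this solves to e^{sigma^2} = (1 + sqrt(1 + 4 s^2/m^2)) / 2.
    """

    median: float
    sd: float

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        r = (self.sd / self.median) ** 2
        t = (1.0 + math.sqrt(1.0 + 4.0 * r)) / 2.0
        return math.sqrt(math.log(t))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, size=n)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults reproduce the control condition: length median 53 px, SD 11 px;
    width median 23 px, SD 2 px.  ``border_margin`` > 0 keeps every cell at
    least that far from the canvas edge (clean scenes for benchmarking);
    with margin 0 border-clipped cells arise naturally.
    """

    canvas_size: tuple[int, int] = (512, 512)  # (H, W)
    n_cells: int = 20
    length_distribution: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(median=53.0, sd=11.0)
    )
    width_distribution: LogNormalSpec = field(
        default_factory=lambda: LogNormalSpec(median=23.0, sd=2.0)
    )
    fraction_fission: float = 0.0
    fraction_filament: float = 0.0
    # max foreign-mask intrusion into a cell's tight box, as a fraction of
    # the cell's own area, before the cell is labelled "overlapping"
    overlap_allowance: float = 0.02
    noise_sigma: float = 4.0         # additive Gaussian, 8-bit intensity units
    blur_sigma: float = 0.8          # mild PSF stand-in, px
    background_level: int = 60
    cell_level: int = 160
    border_margin: float = 0.0
    # minimum clearance between cell masks, px; 0 lets cells sit adjacent
    # (blur can then fuse near neighbours, as crowded fields do)
    min_separation: float = 0.0
    max_attempts_per_cell: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_fission", "fraction_filament"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        H, W = self.canvas_size
        if H < 8 or W < 8:
            raise ValueError(f"canvas {self.canvas_size} too small to place a cell")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not (0 <= self.background_level <= 255 and 0 <= self.cell_level <= 255):
            raise ValueError("intensity levels must be 8-bit (0..255)")


@dataclass
class Scene:
    """A rendered scene: 8-bit image, ground-truth cells, per-cell masks."""

    image: np.ndarray                # (H, W) uint8
    cells: list[CellGT]
    masks: list[np.ndarray]          # boolean, same shape as image
    config: SceneConfig
    n_requested: int = 0             # cells asked for (placement may fall short)

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.masks):
            raise ValueError("every CellGT must have a mask")
        for c, m in zip(self.cells, self.masks):
            if m.shape != self.image.shape:
                raise ValueError(f"mask of cell {c.id} does not match canvas")
            if not m.any():
                raise ValueError(f"mask of cell {c.id} is empty")


def render_capsule(
    length: float,
    width: float,
    angle: float,
    center: tuple[float, float],
    canvas: tuple[int, int],
) -> np.ndarray:
    """Rasterize one capsule as a boolean mask.

    The capsule is the set of points within ``width/2`` of the central
    segment of length ``length - width`` oriented at ``angle`` degrees
    through ``center``; it is clipped at the canvas borders.
    """
    if not (length >= width > 0):
        raise ValueError(f"need length >= width > 0, got {length}, {width}")
    H, W = canvas
    cx, cy = center
    half = (length - width) / 2.0
    theta = math.radians(angle)
    ux, uy = math.cos(theta), math.sin(theta)

    # Work on the tight region around the capsule only.
    r = length / 2.0 + 1.0
    x0, x1 = max(0, int(cx - r)), min(W, int(math.ceil(cx + r)) + 1)
    y0, y1 = max(0, int(cy - r)), min(H, int(math.ceil(cy + r)) + 1)
    mask = np.zeros((H, W), dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask

    ys, xs = np.mgrid[y0:y1, x0:x1]
    # pixel (x, y) spans [x, x+1) x [y, y+1); its center sits at +0.5
    dx = xs + 0.5 - cx
    dy = ys + 0.5 - cy
    # Distance from each pixel center to the central segment.
    t = np.clip(dx * ux + dy * uy, -half, half)
    d2 = (dx - t * ux) ** 2 + (dy - t * uy) ** 2
    mask[y0:y1, x0:x1] = d2 <= (width / 2.0) ** 2
    return mask


def capsule_bbox(cell: CellGT) -> tuple[float, float, float, float]:
    """Axis-aligned bounding box (x_min, y_min, x_max, y_max) of the ideal capsule."""
    theta = math.radians(cell.angle)
    half = (cell.length - cell.width) / 2.0
    rx = abs(half * math.cos(theta)) + cell.width / 2.0
    ry = abs(half * math.sin(theta)) + cell.width / 2.0
    cx, cy = cell.center
    return cx - rx, cy - ry, cx + rx, cy + ry


def _tight_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _place(
    rng: np.random.Generator,
    cfg: SceneConfig,
    length: float,
    width: float,
    occupied: np.ndarray,
) -> Optional[tuple[float, float, float, np.ndarray]]:
    """Rejection-sample a non-overlapping placement.

    Returns (cx, cy, angle, mask) or None after the attempt budget; the
    occupancy canvas makes the overlap check O(capsule area).
    """
    H, W = cfg.canvas_size
    m = cfg.border_margin
    for _ in range(cfg.max_attempts_per_cell):
        angle = float(rng.uniform(0.0, 180.0))
        if m > 0:
            r = length / 2.0 + m
            if 2 * r >= min(H, W):
                r = min(H, W) / 2.0 - 1.0
            cx = float(rng.uniform(r, W - r))
            cy = float(rng.uniform(r, H - r))
        else:
            cx = float(rng.uniform(0.0, W))
            cy = float(rng.uniform(0.0, H))
        mask = render_capsule(length, width, angle, (cx, cy), (H, W))
        if not mask.any():
            continue
        sep = cfg.min_separation
        probe = mask if sep <= 0 else render_capsule(
            length + 2 * sep, width + 2 * sep, angle, (cx, cy), (H, W))
        x0, y0, x1, y1 = _tight_box(probe)
        if np.logical_and(probe[y0:y1, x0:x1], occupied[y0:y1, x0:x1]).any():
            continue
        return cx, cy, angle, mask
    return None


def generate_scene(config: SceneConfig) -> Scene:
    """Generate one scene deterministically from (config, config.seed).

    Exactly ``n_cells`` ground-truth records are produced when placement
    succeeds; fission pairs are rendered as two collinear capsules separated
    by a 1-2 px septum gap, filaments as >= 3 chained collinear capsules
    fused into one mask.  After composition, cells whose mask touches the
    border are relabelled ``border_clipped`` and cells whose tight box is
    intruded by a neighbour's mask beyond ``overlap_allowance`` are
    relabelled ``overlapping``; noise and blur are applied last.
    """
    from scipy.ndimage import gaussian_filter

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.canvas_size

    # Per-cell category draws; fission members come in pairs, so round the
    # Bernoulli count down to even.
    u = rng.random(cfg.n_cells)
    n_fission = int((u < cfg.fraction_fission).sum())
    n_fission -= n_fission % 2
    n_filament_cells = int(
        ((u >= cfg.fraction_fission)
         & (u < cfg.fraction_fission + cfg.fraction_filament)).sum()
    )

    cells: list[CellGT] = []
    masks: list[np.ndarray] = []
    occupied = np.zeros((H, W), dtype=bool)
    next_id = 0
    placed_budget = cfg.n_cells

    def lengths(n: int) -> np.ndarray:
        return cfg.length_distribution.sample(rng, n)

    def widths(n: int) -> np.ndarray:
        return cfg.width_distribution.sample(rng, n)

    # --- fission pairs: two collinear capsules with a septum gap ---
    for _ in range(n_fission // 2):
        if placed_budget < 2:
            break
        L1, L2 = lengths(2)
        w = float(widths(1)[0])
        L1, L2 = max(L1, w + 1), max(L2, w + 1)
        gap = float(rng.uniform(1.0, 2.0))
        total = L1 + gap + L2
        pl = _place(rng, cfg, total, w, occupied)
        if pl is None:
            continue
        cx, cy, angle, _ = pl
        theta = math.radians(angle)
        ux, uy = math.cos(theta), math.sin(theta)
        # member centers offset along the common axis
        o1 = -(total / 2.0) + L1 / 2.0
        o2 = (total / 2.0) - L2 / 2.0
        for L, o in ((L1, o1), (L2, o2)):
            c = (cx + o * ux, cy + o * uy)
            m = render_capsule(L, w, angle, c, (H, W))
            if not m.any():
                continue
            cells.append(CellGT(next_id, c, angle, float(L), w, FISSION))
            masks.append(m)
            occupied |= m
            next_id += 1
            placed_budget -= 1

    # --- filaments: >= 3 chained collinear capsules fused into one mask ---
    n_filaments_placed = 0
    while n_filament_cells > 0 and placed_budget > 0:
        n_links = int(rng.integers(3, 6))
        link_L = lengths(n_links)
        w = float(widths(1)[0])
        link_L = np.maximum(link_L, w + 1)
        gap = 1.0  # links nearly touching; mask fuses after blur anyway
        total = float(link_L.sum() + gap * (n_links - 1))
        pl = _place(rng, cfg, total, w, occupied)
        if pl is None:
            n_filament_cells -= 1
            continue
        cx, cy, angle, _ = pl
        theta = math.radians(angle)
        ux, uy = math.cos(theta), math.sin(theta)
        fused = np.zeros((H, W), dtype=bool)
        off = -total / 2.0
        for L in link_L:
            c = (cx + (off + L / 2.0) * ux, cy + (off + L / 2.0) * uy)
            fused |= render_capsule(float(L), w, angle, c, (H, W))
            off += float(L) + gap
        if fused.any():
            # one ground-truth object; length = end-to-end chain extent
            cells.append(CellGT(next_id, (cx, cy), angle, total, w, FILAMENT))
            masks.append(fused)
            occupied |= fused
            next_id += 1
            placed_budget -= 1
            n_filaments_placed += 1
        n_filament_cells -= 1

    # --- singles ---
    while placed_budget > 0:
        L = float(lengths(1)[0])
        w = float(widths(1)[0])
        L = max(L, w + 0.5)
        pl = _place(rng, cfg, L, w, occupied)
        if pl is None:
            break  # placement failure: report how many cells were placed
        cx, cy, angle, m = pl
        cells.append(CellGT(next_id, (cx, cy), angle, L, w, SINGLE))
        masks.append(m)
        occupied |= m
        next_id += 1
        placed_budget -= 1

    # --- post-composition relabelling ---
    # Masks never overlap by construction, so the "overlapping" label means
    # a neighbour's mask intrudes into this cell's tight box by more than
    # overlap_allowance of the cell's own area — the crop would then carry
    # foreign pixels and its box would not represent this cell alone.
    boxes = [_tight_box(m) for m in masks]
    overl: set[int] = set()
    for i in range(len(cells)):
        xi0, yi0, xi1, yi1 = boxes[i]
        allow = cfg.overlap_allowance * masks[i].sum()
        for j in range(len(cells)):
            if j == i or (i in overl and j in overl):
                continue
            xj0, yj0, xj1, yj1 = boxes[j]
            if xj0 >= xi1 or xi0 >= xj1 or yj0 >= yi1 or yi0 >= yj1:
                continue
            if cells[i].category == FISSION and cells[j].category == FISSION:
                continue  # siblings sit close by design
            if masks[j][yi0:yi1, xi0:xi1].sum() > allow:
                overl.add(i)
    for i, (c, m) in enumerate(zip(cells, masks)):
        if c.category in (FISSION, FILAMENT):
            continue
        if _touches_border(m):
            cells[i] = replace(c, category=BORDER)
        elif i in overl:
            cells[i] = replace(c, category=OVERLAP)

    # --- compose image ---
    img = np.full((H, W), float(cfg.background_level))
    for m in masks:
        img[m] = cfg.cell_level
    if cfg.blur_sigma > 0:
        img = gaussian_filter(img, cfg.blur_sigma)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return Scene(image=img, cells=cells, masks=masks, config=cfg,
                 n_requested=cfg.n_cells)


# Reason taxonomy for non-representative cells
_REASON = {FISSION: "fission", FILAMENT: "filament_partial",
           BORDER: "border", OVERLAP: "overlap"}


def export_annotations(scene: Scene) -> tuple[list[dict], list[dict]]:
    """Detection ground truth and crop-validity labels for a scene.

    Detection ground truth contains ONLY cells whose bounding box represents
    the full cell extent (category ``single``) — mirroring annotation of
    full-length cells as a single class.  Every cell additionally receives
    a validity record: ``representative`` iff single, otherwise
    ``non_representative`` with a reason.

    Returns ``(detection_boxes, validity_records)`` where each detection box
    is ``{"cell_id", "x_min", "y_min", "x_max", "y_max"}`` (half-open,
    mask-tight) and each validity record is
    ``{"cell_id", "label", "reason"}``.
    """
    det: list[dict] = []
    validity: list[dict] = []
    for cell, mask in zip(scene.cells, scene.masks):
        ys, xs = np.nonzero(mask)
        box = {
            "cell_id": cell.id,
            "x_min": int(xs.min()),
            "y_min": int(ys.min()),
            "x_max": int(xs.max()) + 1,
            "y_max": int(ys.max()) + 1,
        }
        if cell.category == SINGLE:
            det.append(box)
            validity.append({"cell_id": cell.id, "label": "representative",
                             "reason": "none"})
        else:
            validity.append({"cell_id": cell.id, "label": "non_representative",
                             "reason": _REASON[cell.category]})
    return det, validity


# Condition presets matching the reported computational measurement
# distributions: control length median 53 px / SD 11 px, acidic length
# median 75 px / SD 21 px; both share width median 23 px / SD 2 px.
CONTROL_PRESET = SceneConfig(
    length_distribution=LogNormalSpec(median=53.0, sd=11.0),
    width_distribution=LogNormalSpec(median=23.0, sd=2.0),
)
ACIDIC_PRESET = SceneConfig(
    length_distribution=LogNormalSpec(median=75.0, sd=21.0),
    width_distribution=LogNormalSpec(median=23.0, sd=2.0),
)
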