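"""End-to-end orchestration: detect -> filter -> measure -> compare.

A run is described by a :class:`PipelineConfig`; every stage draws its
randomness from a per-stage seed derived from the single global seed (via
``numpy.random.SeedSequence(seed).spawn``), so any stage can be re-run in
isolation and reproduce its output.  The manifest records the config, the
per-stage funnel counts (cells entering/surviving each stage) and content
checksums of the stage outputs, making full-run reproducibility a checksum
comparison.

Conservation of cells holds at every stage:
``n_detected = n_measured + n_rejected + n_unmeasurable`` — every discarded
cell appears in exactly one rejection log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import synthgen
from .classification import Crop, GeometricOracle, filter_crops, CROP_PAD
from .detection import BBox, DetectorParams, detect_cells, iou
from .measurement import CannyParams, measure_all
from .morphostats import ComparisonReport, compare_conditions
from .synthgen import Scene, SceneConfig, generate_scene

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "measure_condition", "stage_seeds"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameters of a full synthetic-benchmark run."""

    control: SceneConfig
    acidic: SceneConfig
    n_scenes_per_condition: int = 10
    detector: DetectorParams = field(default_factory=DetectorParams)
    canny: CannyParams = field(default_factory=CannyParams)
    seed: int = 0
    nm_per_pixel: Optional[float] = None
    out_dir: Optional[str] = None

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        """Build from a config mapping; unknown keys are rejected."""
        def build(tp, sub: dict):
            names = {f.name for f in dataclasses.fields(tp)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(f"unknown keys in {tp.__name__}: {sorted(unknown)}")
            return tp(**sub)

        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(doc)
        for key, tp in (("control", SceneConfig), ("acidic", SceneConfig),
                        ("detector", DetectorParams), ("canny", CannyParams)):
            if key in kw and isinstance(kw[key], dict):
                sub = dict(kw[key])
                for dkey in ("length_distribution", "width_distribution"):
                    if dkey in sub and isinstance(sub[dkey], dict):
                        sub[dkey] = build(synthgen.LogNormalSpec, sub[dkey])
                kw[key] = build(tp, sub)
        return cls(**kw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict[str, int]
    counts: dict[str, int]
    checksums: dict[str, str]
    version: str = "0.1.0"
    failed_stage: Optional[str] = None


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one global seed out to per-stage seeds (documented derivation)."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("synth_control", "synth_acidic", "detect", "stats")
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _crops_from_detections(scene: Scene, pad: int = CROP_PAD
                           ) -> tuple[list[Crop], int]:
    """Detected boxes as crops, linked to the best-IoU ground-truth cell."""
    dets = detect_cells(scene.image)
    gt_boxes = []
    for mask in scene.masks:
        ys, xs = np.nonzero(mask)
        gt_boxes.append(BBox(float(xs.min()), float(ys.min()),
                             float(xs.max()) + 1, float(ys.max()) + 1))
    H, W = scene.image.shape
    crops = []
    for k, d in enumerate(dets):
        best, best_iou = None, 0.1
        for cell, gb in zip(scene.cells, gt_boxes):
            v = iou(d.box, gb)
            if v > best_iou:
                best, best_iou = cell.id, v
        x0, y0 = max(0, int(d.box.x_min) - pad), max(0, int(d.box.y_min) - pad)
        x1, y1 = min(W, int(d.box.x_max) + pad), min(H, int(d.box.y_max) + pad)
        crops.append(Crop(crop_id=k, pixels=scene.image[y0:y1, x0:x1],
                          box=d.box, cell_id=best))
    return crops, len(dets)


def measure_condition(cfg: SceneConfig, n_scenes: int, seed: int,
                      canny: CannyParams = CannyParams()
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Generate scenes and run detect -> filter -> measure for one condition.

    Returns the measurement table (one row per surviving cell, with ground
    truth attached for benchmarking) and the funnel counts.
    """
    rows = []
    counts = {"n_detected": 0, "n_rejected": 0, "n_unmeasurable": 0,
              "n_measured": 0}
    rng = np.random.default_rng(seed)
    for s in range(n_scenes):
        scene_cfg = dataclasses.replace(cfg, seed=int(rng.integers(2 ** 31)))
        scene = generate_scene(scene_cfg)
        crops, n_det = _crops_from_detections(scene)
        counts["n_detected"] += n_det
        oracle = GeometricOracle(scene)

        def classify(crop, _oracle=oracle):
            if crop.cell_id is None:
                raise ValueError("detection matches no ground-truth cell")
            return _oracle(crop)

        kept, rejlog = filter_crops(crops, classify)
        counts["n_rejected"] += len(rejlog)
        meas, unlog = measure_all(kept, canny, source_image=f"scene{s}")
        counts["n_unmeasurable"] += len(unlog)
        counts["n_measured"] += len(meas)
        truth = {c.id: c for c in scene.cells}
        for m in meas:
            t = truth[m.cell_id]
            rows.append({"cell_id": f"s{s}c{m.cell_id}",
                         "image_id": m.source_image,
                         "length_px": m.length_px, "width_px": m.width_px,
                         "method": m.method,
                         "true_length_px": t.length, "true_width_px": t.width})
    return pd.DataFrame(rows), counts


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, ComparisonReport]:
    """Execute the full synthetic two-condition pipeline.

    Stage order: generate+detect+filter+measure per condition, then the
    statistical comparison.  Outputs are persisted to ``config.out_dir``
    when set; the manifest records funnel counts and checksums.
    """
    seeds = stage_seeds(config.seed)
    counts: dict[str, int] = {}
    checksums: dict[str, str] = {}
    failed = None
    report = None
    try:
        tables = {}
        for cond in ("control", "acidic"):
            cfg = getattr(config, cond)
            tab, cnt = measure_condition(cfg, config.n_scenes_per_condition,
                                         seeds[f"synth_{cond}"], config.canny)
            if tab.empty:
                raise RuntimeError(f"no cells survived the {cond} pipeline")
            tables[cond] = tab
            for k, v in cnt.items():
                counts[f"{cond}_{k}"] = v
            checksums[f"measurements_{cond}"] = _checksum(
                tab.to_dict(orient="list"))
            if config.out_dir:
                out = Path(config.out_dir)
                out.mkdir(parents=True, exist_ok=True)
                tab.to_csv(out / f"measurements_{cond}.csv", index=False)
        report = compare_conditions(tables["control"], tables["acidic"])
        checksums["report"] = _checksum(report.to_dict())
        if config.out_dir:
            (Path(config.out_dir) / "report.json").write_text(
                json.dumps(report.to_dict(), indent=1, default=str))
    except Exception:
        failed = "comparison" if counts else "measurement"
        raise
    finally:
        manifest = RunManifest(config=asdict(config), seed=config.seed,
                               stage_seeds=seeds, counts=counts,
                               checksums=checksums, failed_stage=failed)
        if config.out_dir:
            Path(config.out_dir).mkdir(parents=True, exist_ok=True)
            (Path(config.out_dir) / "manifest.json").write_text(
                json.dumps(asdict(manifest), indent=1, default=str))
    return manifest, report
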