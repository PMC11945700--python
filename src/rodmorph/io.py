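"""File-format plumbing shared by the pipeline stages.

Conventions: all coordinates on disk use the 0-based half-open convention;
the COCO writer converts to COCO's ``(x, y, width, height)`` boxes on
output and back on input.  Images are 8-bit grayscale PNG or TIFF; 16-bit
input is converted by a linear rescale of the full 16-bit range with a
logged warning.  Schema violations are reported with row/field context,
never silently coerced.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .detection import BBox, Detection

logger = logging.getLogger("rodmorph")

__all__ = [
    "read_image",
    "write_image",
    "read_coco",
    "write_coco",
    "read_csv_table",
    "write_csv_table",
    "read_yaml_config",
    "read_spectra_csv",
    "read_plate_csv",
]

PathLike = Union[str, Path]


def read_image(path: PathLike) -> np.ndarray:
    """Read a grayscale image as uint8; 16-bit input is linearly rescaled.

    The 16-bit -> 8-bit conversion is ``round(v * 255 / 65535)``.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.ptp(arr[..., :3], axis=2).max() == 0:
            arr = arr[..., 0]  # gray stored as RGB
        else:
            raise ValueError(f"{path}: expected a grayscale image")
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit image rescaled to 8-bit "
                      "(linear, v*255/65535)")
        arr = np.round(arr.astype(float) * 255.0 / 65535.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return arr


def write_image(path: PathLike, image: np.ndarray) -> None:
    import imageio.v3 as iio

    if image.dtype != np.uint8 or image.ndim != 2:
        raise ValueError("write_image expects a 2-D uint8 array")
    iio.imwrite(path, image)


def write_coco(path: PathLike, boxes_by_image: dict[str, list[dict]],
               image_sizes: dict[str, tuple[int, int]] | None = None) -> None:
    """Write detection-style annotations as COCO JSON.

    ``boxes_by_image`` maps image id -> list of dicts with half-open
    x_min/y_min/x_max/y_max and optional score/cell_id; boxes are stored as
    COCO ``[x, y, width, height]``.
    """
    images, anns = [], []
    ann_id = 1
    for k, image_id in enumerate(sorted(boxes_by_image), start=1):
        h, w = (image_sizes or {}).get(image_id, (0, 0))
        images.append({"id": k, "file_name": str(image_id),
                       "height": int(h), "width": int(w)})
        for b in boxes_by_image[image_id]:
            x0, y0 = float(b["x_min"]), float(b["y_min"])
            bw, bh = float(b["x_max"]) - x0, float(b["y_max"]) - y0
            ann = {"id": ann_id, "image_id": k, "category_id": 1,
                   "bbox": [x0, y0, bw, bh], "area": bw * bh, "iscrowd": 0}
            if "score" in b:
                ann["score"] = float(b["score"])
            if "cell_id" in b:
                ann["cell_id"] = int(b["cell_id"])
            anns.append(ann)
            ann_id += 1
    doc = {"images": images, "annotations": anns,
           "categories": [{"id": 1, "name": "cell"}]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco(path: PathLike) -> dict[str, list[dict]]:
    """Read COCO JSON back into half-open-box dicts keyed by image name."""
    doc = json.loads(Path(path).read_text())
    name_of = {im["id"]: im["file_name"] for im in doc["images"]}
    out: dict[str, list[dict]] = {n: [] for n in name_of.values()}
    for ann in doc["annotations"]:
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise ValueError(
                f"annotation id {ann['id']}: degenerate box {ann['bbox']}")
        rec = {"x_min": float(x), "y_min": float(y),
               "x_max": float(x + w), "y_max": float(y + h)}
        for extra in ("score", "cell_id"):
            if extra in ann:
                rec[extra] = ann[extra]
        out[name_of[ann["image_id"]]].append(rec)
    return out


def detections_to_records(dets: list[Detection]) -> list[dict]:
    return [{"image_id": d.source_image, "x_min": d.box.x_min,
             "y_min": d.box.y_min, "x_max": d.box.x_max,
             "y_max": d.box.y_max, "score": d.score} for d in dets]


def records_to_detections(records: list[dict]) -> list[Detection]:
    return [Detection(BBox(r["x_min"], r["y_min"], r["x_max"], r["y_max"]),
                      score=float(r["score"]),
                      source_image=str(r.get("image_id", ""))) for r in records]


def write_csv_table(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_csv_table(path: PathLike, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_yaml_config(path: PathLike) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return doc


def read_spectra_csv(path: PathLike) -> pd.DataFrame:
    """Spectra table: sample_id, replicate, wavelength_nm, rfi[, blank_rfi]."""
    df = read_csv_table(path, required=("sample_id", "replicate",
                                        "wavelength_nm", "rfi"))
    if (df["rfi"] < 0).any():
        bad = df.index[df["rfi"] < 0][0]
        raise ValueError(f"{path}: negative rfi at row {bad}")
    return df


def read_plate_csv(path: PathLike):
    """Plate-reader table: time_h column, then one column per replicate."""
    from .assays import GrowthCurve

    df = read_csv_table(path, required=("time_h",))
    reps = [c for c in df.columns if c != "time_h"]
    if len(reps) < 2:
        raise ValueError(f"{path}: need >= 2 replicate columns")
    return GrowthCurve(time=df["time_h"].to_numpy(),
                       od600=df[reps].to_numpy().T)
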