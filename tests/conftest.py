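import dataclasses

import numpy as np
import pytest

from rodmorph.classification import Crop
from rodmorph.detection import BBox
from rodmorph.synthgen import (
    CONTROL_PRESET,
    SceneConfig,
    generate_scene,
    render_capsule,
)


def clean_capsule_crop(length, width, angle, center=(100.3, 100.7),
                       canvas=(240, 240), pad=2, fg=160, bg=60):
    """Noiseless capsule rendered and cropped the way the pipeline crops."""
    mask = render_capsule(length, width, angle, center, canvas)
    img = np.where(mask, fg, bg).astype(np.uint8)
    ys, xs = np.nonzero(mask)
    box = BBox(float(xs.min()), float(ys.min()),
               float(xs.max()) + 1, float(ys.max()) + 1)
    H, W = canvas
    x0, y0 = max(0, int(box.x_min) - pad), max(0, int(box.y_min) - pad)
    x1, y1 = min(W, int(box.x_max) + pad), min(H, int(box.y_max) + pad)
    return Crop(0, img[y0:y1, x0:x1], box), mask


@pytest.fixture(scope="session")
def mixed_scene():
    """One scene containing singles, fission pairs and border-clipped cells."""
    cfg = dataclasses.replace(
        CONTROL_PRESET, n_cells=14, canvas_size=(420, 420),
        fraction_fission=0.3, seed=11)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def clean_single_scene():
    """One well-separated non-clipped capsule on a mildly noisy background."""
    cfg = dataclasses.replace(
        CONTROL_PRESET, n_cells=1, canvas_size=(220, 220),
        border_margin=12, seed=3)
    return generate_scene(cfg)
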