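# Methods

This note records the model behind `rodmorph`, the default parameters and
why they were chosen, the numerical conventions, and the limitations.

## 1. Cell model and synthetic scenes

### Geometry

A cell is a **capsule** (spherocylinder projected to 2-D): the set of pixels
within distance W/2 of a segment of length L − W, so the overall extent is
L × W. Rasterization uses a half-open pixel convention — pixel (x, y) covers
[x, x+1) × [y, y+1) with its center at (x+0.5, y+0.5). With this convention
an axis-aligned capsule of nominal size 60 × 20 px occupies exactly a
60 × 20 px bounding box and its pixel area matches the analytic capsule area
to well under 1 %; with integer-center sampling both are biased high.

### Dimension distributions

Lengths and widths are log-normal, parameterized by **median m** and
**standard deviation s** (both in px), the two numbers a morphometric study
typically reports. Solving s² = m²e^{σ²}(e^{σ²} − 1) gives
e^{σ²} = (1 + √(1 + 4s²/m²))/2 and μ = ln m. Presets:

| preset  | length (m, s) | width (m, s) |
|---------|---------------|--------------|
| control | 53, 11 px     | 23, 2 px     |
| acidic  | 75, 21 px     | 23, 2 px     |

The two presets differ only in length: elongation under acid stress with
conserved width is the biological signature the statistics are designed to
detect, and sharing the width distribution is what makes the expected
width-comparison outcome "no difference".

### Scene composition (`SceneConfig` defaults)

| parameter | default | rationale |
|---|---|---|
| `canvas_size` | 512 × 512 px | a few dozen cells at the preset scale without crowding |
| `n_cells` | 20 | moderate density; placement rarely exhausts attempts |
| `fraction_fission` | 0.2 | a visible minority of dividing cells |
| `fraction_filament` | 0.0 | filaments are an opt-in stress morphology |
| `overlap_allowance` | 0.02 | foreign-mask area fraction tolerated in a cell's box before it is labelled `overlapping` |
| `min_separation` | 0 px | extra clearance during placement; raise (e.g. 8) to guarantee blur cannot fuse neighbours |
| `border_margin` | 0 px | 0 permits border-clipped cells, which the validity filter must then catch |
| `background`, `cell` | 60, 160 | mid-gray cells on dark background, well separated but not saturated |
| `blur_sigma` | 0.8 px | optical/detector point-spread softening |
| `noise_sigma` | 4.0 | additive Gaussian sensor noise; SNR ≈ 25 on the foreground step |
| `max_attempts` | 200 per cell | rejection-sampling budget |

Placement is rejection sampling against an occupancy canvas, so **masks are
disjoint by construction**. The `overlapping` validity label therefore uses a
box-intrusion rule — foreign mask pixels inside a cell's tight bounding box
exceeding `overlap_allowance` × its own area — rather than a mask-IoU rule,
which would never fire. Fission pairs are two collinear capsules with a
1–2 px gap; filaments are 3–5 fused links recorded as one cell whose length
is the chain extent. Per-scene ground truth records every cell's center,
angle, true L and W, category, and a validity label
(`representative` / `non_representative` with reason: border, fission,
filament, overlap). Detection ground truth exports boxes for isolated
full-length cells only, because those are the valid measurement targets.

### What the generator emulates — and what it does not

Emulated: capsule geometry, log-normal size variation, division figures,
border clipping, proximity/overlap, optical blur, additive sensor noise.
Not emulated: real SEM surface texture, shading and charging artifacts,
staining variability, deformed or bent cells, dense clumps requiring
instance segmentation. The generator exists to give exact ground truth for
validating the pipeline, not to be photorealistic.

## 2. Detection

Classical pipeline: subtract the image median (background estimate),
threshold with Otsu, open with a disc (radius 5 px — smaller than the
narrowest preset cell radius, so it removes noise specks without eroding
cells apart), then connected components filtered by area ≥ 120 px²
(≈ 25 % of the smallest preset cell) and solidity ≥ 0.5 (capsules are
convex; very concave blobs are merge artifacts). The detection score is the
component's solidity. A contrast sanity check (foreground mean at least
4 background SDs above background mean) returns zero detections on
effectively empty images instead of thresholding noise.

Evaluation: detections are matched to ground-truth boxes greedily in score
order at a box-IoU threshold; AP is the all-points area under the
precision–recall curve (precision envelope); mAP averages AP over IoU
0.50:0.05:0.95. The implementation is verified in tests against an
independent brute-force matcher and against a hand-worked example
(2 TP + 1 FP + 1 FN interleaved → AP = 0.5·1 + 0.5·(2/3) ≈ 0.833).

## 3. Crop validity filtering

Images can be cut into non-overlapping 250 × 250 px tiles (partial tiles
dropped). Each detected cell yields a crop (box padded by 2 px so edges are
visible to Canny). A crop is **representative** only if it contains a
single, full-length, essentially isolated cell. The filter takes any
callable `crop -> CropLabel`, so backends are pluggable:

- `GeometricOracle` — exact labels from synthetic ground truth (single
  category, mask inside the box, foreign intrusion ≤ allowance × area).
- `LogisticCropClassifier` — scikit-learn logistic regression on shape
  features (box aspect, fill fraction, four border-contact fractions, a
  4-bin edge-density profile), trainable on oracle-labelled synthetic crops.

A classifier exception on one crop marks that crop rejected (with the error
recorded) and the batch continues. Accounting is conserved:
n_detected = n_measured + n_rejected + n_unmeasurable.

## 4. Edge-refined measurement

Per crop: Gaussian-smoothed Canny (σ = 1.5 px; hysteresis thresholds
"auto" = 0.66 and 1.33 × the smoothed crop median, scaled to gradient
units — the common Canny auto-threshold heuristic). PCA of the edge-point
cloud gives the cell axis. Then:

- **length** = trimmed axial extent — the mean of the 3 outermost edge-point
  projections at each end (robust to single stray edge pixels) — plus a
  calibration term 3.84 − 3.04·a px;
- **width** = 2 × median |perpendicular offset| over the central 60 % of the
  axis (flanks only, avoiding the end caps) plus 2.40 − 1.69·a px;

where a = |cos φ| + |sin φ| ∈ [1, √2] is the grid anisotropy of axis angle
φ. The calibration is linear in a because the raster over/under-shoot of
edge positions varies smoothly between axis-aligned (a = 1) and diagonal
(a = √2) orientations; the two constants per dimension were fit once on
randomly oriented clean capsules spanning the preset size range and are
fixed package constants, leaving residual RMSE ≈ 0.2–0.3 px. Near-circular
crops (axial extent / raw length > 0.85) have no usable flank region, so
width falls back to a trimmed minor-axis extent with the length calibration.
Crops with fewer than 3 flank edge points per side fall back to
`bbox_only` (box dimensions, no refinement); crops whose edge map is empty
are logged `unmeasurable`. Every measurement records its method and the
box dimensions alongside the refined ones.

## 5. Statistics

- **Summaries**: n, median, mean, SD, quartiles per dimension.
- **Normality gate**: Shapiro–Wilk (n ≥ 3) and D'Agostino–Pearson (n ≥ 20);
  verdict `non_normal` if either p < 0.05 — justifying the nonparametric
  test for skewed dimension data.
- **Mann–Whitney U**: exact null distribution when n_x·n_y ≤ 400 with no
  ties, otherwise normal approximation with tie correction and continuity
  correction (scipy). Identical constant samples are flagged degenerate
  with p = 1 rather than raising. Verified against brute-force pair
  counting in tests.
- **Percent change of medians** uses floor, matching the convention of
  reporting conservative integer percentages (53 → 75 px is +41 %).
- **Agreement** with ground truth is RMSE (plus bias and max error) per
  dimension, joined on cell id.

## 6. Companion assays

- **Laurdan GP** = (RFI₄₄₀ − RFI₄₉₀)/(RFI₄₄₀ + RFI₄₉₀) from an emission
  spectrum. Wavelengths are matched to the nearest sampled point (ties take
  the lower wavelength); optional blank spectra are subtracted with
  intensities floored at 0 so GP stays within [−1, 1].
- **Growth curves**: mean and sample SD (ddof = 1) of OD600 per timepoint
  over ≥ 2 replicates.

## 7. Reproducibility and numerical conventions

- All randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`, giving independent per-stage streams
  (scene generation per condition, detection, statistics); derived seeds
  are reduced mod 2³¹ to stay in the portable range.
- Boxes are half-open `[x_min, x_max) × [y_min, y_max)` everywhere; COCO
  interchange converts to/from (x, y, w, h).
- Images are 8-bit grayscale internally; 16-bit inputs are rescaled by
  255/65535 with a warning; color inputs are rejected (gray-as-RGB
  accepted).
- Pipeline runs emit a manifest (config echo, stage seeds, funnel counts,
  SHA-256 prefixes of outputs), so a run is reproducible from
  (config, seed) alone.
- Benchmark problem sizes in the tests and the acceptance script (e.g.
  100 single-cell 260 × 260 scenes for measurement fidelity) are package
  choices balancing statistical resolution against runtime; they are not
  tied to any particular dataset.

## 8. Design decisions

- Library-first with a thin `click` CLI; each subcommand wraps one library
  call and does file plumbing only.
- Canny and morphology come from scikit-image, statistics from scipy,
  the learned crop filter from scikit-learn — standard primitives are not
  reimplemented; the package's own code is the geometry, calibration,
  labelling rules and orchestration.
- Configuration objects are frozen dataclasses validating their invariants
  in `__post_init__`; unknown YAML keys are rejected recursively so typos
  fail loudly.

## 9. Limitations

- The measurement calibration constants were fit on synthetic capsules;
  real micrographs need a pixel-size calibration and may need refitting.
- The classical detector assumes bright cells on a darker, roughly uniform
  background; it will not separate touching cells (mitigated upstream by
  the validity filter discarding overlapped crops).
- The logistic crop classifier is a baseline; the filter contract accepts
  any stronger learned backend.
- Filament length is the straight chain extent, which under-reports true
  arc length for curved filaments (synthetic filaments are straight).
- Statistical utilities assume independent cells; no mixed-effects
  modelling of scene- or replicate-level clustering.
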