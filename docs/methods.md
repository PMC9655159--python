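# Methods

This note documents the model implemented by `pigpen`, the default
parameters and their rationale, what the synthetic data generator does and
does not emulate, the numerical conventions, and known limitations.

## Model

All stages operate on 8-bit grayscale frames from a fixed camera and on
detection boxes supplied by an external detector (or the test oracle).

### Background estimation (`pigpen.background`)

The background image `B` is initialized to the first frame. On each update,
every pixel *outside* all detection boxes moves one intensity step toward the
reference (`B_{t+1} = B_t + sign(frame − B_t)`), clamped to [0, 255]. Pixels
inside boxes either hold their value (default) or are set to the frame mean.
The ±1 step rule bounds per-frame change, guarantees exact convergence to a
static scene within 255 updates, and makes the estimate immune to brief
occlusions or detector noise. The reference may alternatively be the previous
frame (`compare="prev_frame"`). The difference image is `D = |frame − B|`.

### Facility (occlusion) estimation (`pigpen.facility`)

`F` starts saturated at 255. Per frame, each retained detection box
decrements the pixels within it whose difference value exceeds the box's mean
difference — evidence that an animal body actually covered that pixel. Boxes
whose mean difference falls below the global frame mean are treated as
detector false positives and skipped. Every `calibration_interval` frames, a
calibration step resets pixels above the `noise_ceiling` (and their 8
neighbors) to 255, erasing slow noise accumulation. After enough traversal,
saturated pixels within the animals' range mark fixed structures. With
ceiling 245, a pixel must be hit at least 10 times per interval to stay below
saturation — the interval therefore scales the map's sensitivity.

### NPPS foreground segmentation (`pigpen.npps`)

A per-pixel threshold map `T` is initialized everywhere to the Otsu threshold
of the first difference image (ties broken toward the smallest threshold;
degenerate single-class images give 0, then clamp to the floor). Per frame,
thresholds inside boxes that exceed the local difference decrement by 1;
thresholds outside boxes that fall below it increment by 1. `T` is clamped to
[10, 245]: the floor keeps sensor noise from ever being foreground, the
ceiling keeps pixels recoverable. Foreground is `D > T`, strictly.

### Composite channels (`pigpen.composite`)

Four derived single-channel images, each padded 32 rows at the bottom:

- **A** — CLAHE-equalized gray with facility pixels forced to 255 (pad 255);
- **B** — difference image with facility pixels forced to 0 (pad 0);
- **C** — gray where foreground, 0 elsewhere;
- **D** — the complement: gray where background, 0 where foreground.

C and D partition the gray image (`C + D = gray` pixelwise). Any three
distinct channels stack into a 3-plane detector input; the preset
`composite-X` uses the three channels other than X. CLAHE is implemented
from scratch (clip limit scaled by tile area, clipped excess redistributed
evenly, per-tile LUTs blended bilinearly between tile centers) because no
OpenCV binding is assumed; with one tile and an unreachable clip limit it
reduces exactly to global histogram equalization, which the tests exploit as
an oracle.

### Perspective normalization (`pigpen.perspective`)

The user marks a floor quadrilateral. The lines through its left and right
sides are extended to the top and bottom frame edges; the frame is padded
horizontally so all four intersections are inside the padded plane; the four
intersections anchor an exact 8×8 direct-linear-transform homography onto the
output rectangle (default 512×288). Boxes map through the warp via the
axis-aligned hull of their projected corners.

### Evaluation (`pigpen.metrics`)

Greedy confidence-ordered VOC matching at IoU ≥ 0.5; precision/recall with
the 0/0 → 0 convention; AP@0.5 with all-point interpolation, reported ×100;
integrated performance = accuracy × FPS rounded to 1 decimal.

## Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| background step | ±1/frame | bounded drift; exact convergence ≤ 255 frames |
| facility calibration interval | 10,000 frames | noise-reset cadence for long deployments; tests lower it to match short clips |
| facility noise ceiling | 245 | a pixel needs ≥ 10 hits/interval to stay marked |
| NPPS bounds | [10, 245] | floor above sensor noise; ceiling keeps pixels recoverable |
| CLAHE clip / grid | 0.6 / (2, 2) | mild local contrast boost without amplifying noise |
| composite bottom pad | 32 rows | detector-input geometry |
| working resolution | 512×288 | 16:9, cheap on embedded hardware |
| NMS IoU | 0.5 | standard duplicate-suppression threshold |

Configuration is a YAML file mirroring `PipelineConfig`; unknown keys are
rejected with the offending key named.

## Synthetic data

`pigpen.synthetic` generates a textured static floor (smoothed Gaussian
texture around intensity 80), dark polygonal occluders drawn *on top of*
animals (a feeder and a pipe by default), bright elliptical animals
(intensity 160–220) patrolling with heading jitter and billiard-style wall
reflection, and per-frame i.i.d. Gaussian pixel noise (σ = 5). Ground truth
includes the clean background, the occluder mask, per-animal full and visible
masks, and tight boxes around visible extents (a fully occluded animal yields
no box). The oracle detector returns truth boxes corrupted by configurable
miss rate, Poisson false positives, and corner jitter.

What it emulates: static geometry, occlusion by fixed structures, animal
motion and crowding, sensor noise, imperfect detection. What it does not:
lighting changes, shadows, animal deformation and contact distortion,
perspective foreshortening, camera compression artifacts, or realistic animal
appearance. The generator's defaults are fixed experimental conditions, not
tuning knobs.

`pen_interior()` defines the evaluation region for facility recovery: the
frame eroded by the largest animal semi-major axis. Animal *centers* reflect
at that margin, so the border band is only grazed tangentially and carries
too few hits per calibration interval to be informative; occlusion recovery
is meaningful only where animals actually travel.

## Numerical conventions

- Image-valued operations round half away from zero (`floor(x + 0.5)`),
  matching common fixed-camera pipelines; metric reporting uses Python's
  `round` at 2 decimals (ratios) or 1 decimal (integrated performance).
- Grayscale conversion is BT.601 luma.
- All difference arithmetic is done in signed integers before taking
  magnitudes; all state images are uint8.
- Every stochastic component takes an explicit seed or `numpy` Generator;
  identical seeds give bitwise-identical outputs, including written PNGs.

## Limitations

- The pipeline is strictly sequential; no multi-core or pipelined overlap.
- The detector itself (a neural network in deployment) is out of scope; the
  package consumes its boxes and produces its training images.
- Facility estimation needs traversal: regions animals never visit are
  indistinguishable from occlusions by construction.
- The perspective module assumes the pen floor is planar and the marked
  quadrilateral's side lines are not horizontal.
- CLAHE matches the standard tile-LUT construction but is not guaranteed
  bit-identical to any particular third-party implementation.
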