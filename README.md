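# pigpen

Static-camera pen video processing: incremental background estimation,
occlusion ("facility") mapping, per-pixel adaptive foreground segmentation,
and composite training-image generation for animal detectors.

## The problem

A fixed surveillance camera watches a livestock pen. Animals move; the floor,
feeders, and pipes do not. Detecting animals from such video is hard because
animals crowd together, pass behind fixed structures, and the oblique camera
makes far animals tiny. But the static geometry is also an opportunity: every
structure occupies the *same pixels in every frame*, so the scene itself can
be learned over time and factored out.

This package implements that idea as a streaming pipeline of cheap per-pixel
update rules, suitable for embedded hardware:

- **Background image** `B` — per-pixel estimate of the animal-free scene.
  Each frame, every pixel outside the detector's boxes moves toward the
  current frame by at most ±1 intensity step, so the estimate converges to
  any stable scene within 255 updates and is robust to transient motion.
- **Difference image** `D = |frame − B|` — per-pixel motion evidence.
- **Facility image** `F` — per-pixel occlusion evidence, initialized to 255
  and decremented wherever animals are *observed* inside detection boxes.
  Pixels that stay saturated mark structures animals never occupy (or pass
  behind). Periodic calibration resets near-saturated pixels and their
  neighbors to suppress accumulated noise.
- **NPPS (non-pig pixel suppression)** — a per-pixel adaptive threshold map
  on `D`, initialized from Otsu's method and nudged ±1 per frame (down inside
  boxes, up outside), yielding a foreground mask that tracks local noise.
- **Composite channels A–D** — single-channel training images derived from
  the above (CLAHE gray with facility pixels whitened; difference with
  facility pixels zeroed; foreground-isolated gray; its complement), stacked
  in triples as drop-in detector input.
- **Perspective normalization** — an automatic four-point projective warp
  that maps a user-chosen floor quadrilateral to an upright rectangle,
  equalizing apparent animal size across depth.
- **Evaluation** — PASCAL-VOC box matching, precision/recall, AP@0.5, and an
  integrated accuracy×speed index.
- **Synthetic scenes** — a seeded generator of textured pens with elliptical
  animals, polygonal occluders, and full ground truth (background, masks,
  tight boxes), plus an oracle detector with configurable miss/false-positive
  /jitter rates. All tests run against this generator; no real video needed.

## Worked example

Simulate a 60-frame pen scene with 4 animals and a detector that misses 10%
of boxes, run the full pipeline on it, and evaluate the detector against
ground truth:

```bash
pigpen simulate --out demo/sim --seed 7 --frames 60 --animals 4 --miss-rate 0.1
```
```
wrote 60 frames to demo/sim
```

```bash
cat > demo/config.yaml <<'YAML'
warp:
  out_size: [256, 144]   # keep the simulated resolution
facility:
  interval: 50           # calibrate every 50 frames (default 10,000)
checkpoint_every: 50
YAML
pigpen run --frames demo/sim/frames --boxes demo/sim/boxes \
           --config demo/config.yaml --out demo/out
```
```
processed 60 frames; outputs in demo/out
```

```bash
pigpen evaluate --preds demo/sim/boxes --truths demo/sim/truth_boxes \
                --width 256 --height 144
```
```
TP	FP	FN	Precision	Recall	AP_0.5
213	0	27	1.00	0.89	88.75
```

The detector missed 27 of 240 boxes (the configured 10% miss rate) and
produced no false positives, so precision is 1.00 and recall 0.89. Inspect
the learned facility image:

```bash
pigpen inspect-state demo/out/facility/final.png
```
```
{"shape": [144, 256], "min": 213, "max": 255, "mean": 252.21, "saturated_255": 28875}
```

Most pixels are still saturated after only 60 frames; pixels traversed by
animals have begun to drop. `demo/out/` also contains per-frame foreground
masks, composite images, per-frame box files, state checkpoints, and a
`manifest.json` listing every artifact.

The same pipeline is available as a library:

```python
from pigpen import PipelineConfig, WarpConfig, run_pipeline
cfg = PipelineConfig(warp=WarpConfig(out_size=(256, 144)))
state = run_pipeline(frames, detector, cfg, "out/")
```

## Reproduction

- `python -m pytest -q tests/` runs the full suite, including one test per
  acceptance criterion in `tests/test_acceptance.py` (published-table metric
  reproduction, exact background convergence, synthetic scene recovery,
  brute-force oracle equivalence, composite-channel invariants, and default
  constants).
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the acceptance targets (integrated performance indices t6 and
  t7) from scratch and writes them as JSON. Both are exact arithmetic;
  expected output: `t6 = 3063.7`, `t7 = 2999.8`.

All randomness is seeded; repeated runs are bitwise identical. See
`docs/methods.md` for the model, parameter defaults, and limitations.
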