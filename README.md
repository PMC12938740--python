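# ma-screen

Classical microaneurysm (MA) detection for colour fundus images.

Microaneurysms — minute round dilatations of retinal capillaries, appearing
as small dark reddish dots of roughly 3–25 px diameter at a working
resolution of 768 × 576 — are the earliest clinically identifiable sign of
diabetic retinopathy, and their per-image count is a key severity indicator.
`ma-screen` implements the classical geometry-based screening pipeline for
this task, aimed at researchers who need a transparent, fully inspectable
baseline detector and a reproducible evaluation harness for comparing
detectors (including external deep-learning ones) on the lesion-counting
problem.

## The pipeline

For an RGB fundus image the classical path runs:

1. **Grayscale blend** — `Gray = 0.5·R + 0.5·G`: the green channel carries
   the strongest red-lesion contrast, the red channel contributes background
   and vessel cues in dark exposures; blue is ignored.
2. **Background subtraction** — a large-kernel (25 px) median filter
   estimates the slowly varying background; the difference image
   `Gray − median(Gray) + 128` isolates small dark lesions below the 128
   mid-level.
3. **CLAHE** — contrast-limited adaptive histogram equalisation restores
   local contrast without over-amplifying bright artefacts.
4. **Adaptive thresholding** — a pixel becomes a lesion candidate when it is
   darker than its 31 × 31 local mean by more than an offset.
5. **Anatomy masking** — the optic disc (brightest smoothed region), blood
   vessels (black top-hat + elongation filter), hard exudates (bright
   outliers) and the field-of-view periphery are excluded; these structures
   are the dominant false-positive sources.
6. **Circular Hough transform** — boundary pixels of the masked candidate
   map vote for circle centres over radii r ∈ [5, 25] px; votes are
   normalised by each radius' ideal perimeter count, so the normalised vote
   serves as a confidence score.
7. **Post-processing** — size/circularity filtering (4πA/P² ≥ 0.6),
   radius bounds, MA counting, and overlay rendering for visual review.

A second, detector-agnostic path refines externally produced bounding-box
predictions (YOLO text format) by confidence filtering and greedy
non-maximum suppression, so any box detector can be evaluated with the same
harness.

Evaluation mirrors standard small-lesion detection practice: one-to-one
greedy matching (centre distance ≤ max(3 px, lesion radius), or box
IoU ≥ 0.5), sensitivity / precision / F1, per-image **count accuracy at 5 %
relative tolerance**, and average precision (single class, so mAP = AP).

Because clinical datasets cannot ship with the package, a synthetic fundus
generator renders annotated scenes with the structure the pipeline assumes —
circular field of view, radial illumination falloff, bright optic disc, dark
random-walk vessel trees, exudate blobs, and sparse soft-profiled
microaneurysms (< 1 % of FOV pixels, matching the severe class imbalance of
screening data) — with exact, deterministic ground truth.

## Worked example

```python
from ma_screen import (PipelineConfig, detect_circles_in_image, evaluate_dataset,
                       render_fundus, sample_scene)
from ma_screen.synth import high_contrast_sampler

spec = sample_scene(high_contrast_sampler(), seed=1)   # one synthetic scene
img, ann = render_fundus(spec)

dets = detect_circles_in_image(img, PipelineConfig())
print(f"planted MAs: {len(ann.ma_entries)}, detected: {len(dets)}")
for d in dets[:3]:
    print(f"  circle at ({d.center_x}, {d.center_y}), r={d.radius}px, score={d.score:.2f}")

report = evaluate_dataset([("scene_1", ann.ma_entries, dets)])
print(f"sensitivity={report.sensitivity:.3f} precision={report.precision:.3f} "
      f"count_accuracy={report.count_accuracy:.2f}")
```

prints

```
planted MAs: 6, detected: 6
  circle at (615, 260), r=5px, score=0.93
  circle at (466, 113), r=7px, score=0.72
  circle at (557, 360), r=7px, score=0.72
sensitivity=1.000 precision=1.000 count_accuracy=1.00
```

Each detection is a circle hypothesis whose score is the fraction of its
ideal perimeter supported by candidate-boundary votes; the report aggregates
matching-based rates and the per-image count check.

The same workflow is available from the shell:

```sh
ma-screen synth --n-images 5 --seed 1 --out data/
ma-screen detect --method cht --in data/images/scene_00001.png --out dets.csv
ma-screen run --in data/images --gt data/labels --out results/
```

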