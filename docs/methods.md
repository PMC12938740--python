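# Methods

This note documents the models, parameter choices and numerical conventions
behind `ma-screen`, and what its synthetic-scene tests do and do not
establish about real fundus images.

## Coordinate and raster conventions

Pixels are indexed 0-based with `x` = column (rightward) and `y` = row
(downward). Bounding boxes are half-open `(x_min, y_min, x_max, y_max)`.
Annotation coordinates are canonicalised to a 10⁻⁶ px grid so coordinate
remappings (e.g. mirror flips) are exactly involutive under floating-point
arithmetic. All rasters are 8-bit unless an operator documents otherwise;
binary maps are strictly two-valued.

## Preprocessing

* **Grayscale blend.** `Gray = round(0.5·R + 0.5·G)` with half-up rounding,
  computed in exact integer arithmetic as `(R + G + 1) // 2`. The blend
  keeps the green channel's red-lesion contrast while retaining red-channel
  background cues; blue carries little retinal structure and is ignored.
* **Median background, kernel 25 px.** The kernel must exceed the largest
  lesion so lesions vanish from the background estimate; 25 px equals the
  upper bound of the MA radius regime. Borders use reflection padding.
* **Difference image.** `Gray − background + 128`, clipped to [0, 255].
  The +128 shift keeps the signed deviation in an 8-bit map; dark lesions
  fall below 128. The encoding is a package convention, recorded here
  because downstream thresholds depend on it.
* **CLAHE.** Per-tile clipped-histogram equalisation with bilinear
  interpolation between tile mappings (scikit-image backend). The clip
  limit is expressed in the convention common in retinal imaging — a
  multiple of the uniform-histogram bin height (default 2.0, tiles 8 × 8,
  256 bins) — and converted internally to the backend's fractional
  convention (`clip/nbins`). A constant image is returned unchanged (its
  histogram is degenerate).
* **Adaptive threshold.** Dark polarity: pixel < local mean − offset over a
  31 × 31 window. Local sums are exact integers (two 1-D box correlations),
  so the output is exactly invariant under global additive shifts. The
  *operator* default offset is 6; the *pipeline* default is 12 because the
  threshold runs on the CLAHE-enhanced difference image, where flat-field
  sensor noise is strongly amplified: with offset 6 roughly 9 % of a blank
  FOV becomes speckle candidates, while lesion contrast after CLAHE is far
  above 12. Both are configurable.

Pipeline order is gray → median → difference → CLAHE → threshold. Running
CLAHE on the difference image (rather than the raw grayscale) was the open
design choice; it makes the threshold operate on a shade-corrected, locally
renormalised map and is the order under which the blank-scene and recovery
properties hold. The order is configurable by composing the operators
directly.

## Anatomy masking

The structures to suppress are given; the detection algorithms are the
package's own choices, each deliberately simple and replaceable behind
`build_exclusion_mask`:

* **Field of view** — largest connected red-channel region above 20, hole
  filled. Red saturates inside the illuminated retina and is near zero
  outside.
* **Optic disc** — peak of the Gaussian-smoothed (σ = half the minimum
  expected radius) grayscale inside the FOV; absent when the peak rises
  less than 30 gray levels above the FOV median; radius from the area of
  the half-prominence region, clipped to the expected range (default
  20–80 px).
* **Vessels** — black top-hat (closing residue, disc radius 7) thresholded
  at 10, keeping components with area ≥ 30 and *elongation* ≥ 3.0.
  Elongation is measured as `P²/(4πA)` (inverse circularity): ~1 for a
  disk, large for any thin or branched shape. An axis-ratio measure was
  rejected because a branched vessel tree forms one connected component
  whose major/minor axis ratio can approach 1; inverse circularity is large
  for the whole tree yet stays ~1 for round lesions, so microaneurysms are
  not swallowed.
* **Exudates** — grayscale above max(99th FOV percentile, FOV median + 40),
  disc region excluded. The contrast floor matters: a pure percentile rule
  would flag ~1 % of a healthy FOV by construction; the floor keeps
  exudate-free scenes nearly empty while true exudates (tens of gray levels
  above background) always exceed it.
* **Periphery** — complement of the FOV eroded by 5 px.

Dilation margins (disc 10, vessels 2, exudates 3 px) are applied once when
the union mask is built; larger margins strictly grow the mask.

## Circular Hough transform

Boundary pixels (1-pixels with a 0 or out-of-frame 4-neighbour) of the
masked candidate map vote over radii 5–25 px, step 1. The perimeter of
radius r is defined as the integer offsets with `round(hypot(dx, dy)) = r` —
an unambiguous rasterisation shared by voting and normalisation, and cheap
for an independent oracle to enumerate. Scores are votes divided by the
ring's ideal offset count, capped at 1, so one threshold (default 0.45)
serves all radii; raw votes would scale with radius. Peaks are accepted
greedily in (score desc, y, x, r asc) order — a fixed tie-break for
determinism — subject to a minimum centre distance (default r_min = 5:
adjacent lesions are kept, concentric duplicates suppressed). The
normalised vote doubles as the confidence for average precision, where a
confidence definition was otherwise unspecified for a geometric detector.

In the full classical run, candidate regions are first filtered by size and
circularity (area within [π·5²/2, 2π·25²], circularity ≥ 0.6), which removes
residual vessel fragments and speckle before voting; detections whose
centre lies in the exclusion mask are dropped, and the radius bounds mean a
lesion of radius 3 px is structurally undetectable by this path.

## Post-processing and evaluation conventions

* Greedy NMS: confidence descending, ties by (y_min, x_min); accept iff IoU
  with every accepted box ≤ threshold (default 0.45). Confidence filter
  default 0.25.
* Matching is greedy one-to-one in descending confidence; greedy was chosen
  over optimal assignment for transparency and is bounded by an exhaustive
  assignment oracle in tests.
* Degenerate rates: 0/0 → 0 for precision, recall and F1.
* Count accuracy at tolerance τ (default 0.05): an image with true count
  t > 0 passes iff |d − t| ≤ τ·t; with t = 0 iff d = 0. This per-image
  relative-count reading is the most direct interpretation of a
  "% tolerance" count accuracy; a lesion-level reading is available by
  combining the matching rates instead.
* Average precision uses all-points interpolation (area under the precision
  envelope); with a single lesion class, mAP = AP. Dataset mAP pools all
  detections ranked by confidence, matching per image.

## Synthetic scene model

The generator produces the statistical structure the pipeline assumes, not
photorealism: quadratic radial illumination falloff (amplitude 0.15),
a plateau-profiled bright optic disc (r = 40 px, +80 gray), a recursive
random-walk vessel tree (5 roots, width 4 px, −45 gray, extremum-blended so
crossings do not double-darken), soft cosine-profiled exudates, and
microaneurysms darkest in green (−contrast in G, −0.6·contrast in R).
MAs default to the cosine profile because hard disks make circle detection
trivially easy; the flag `soft_profile=False` restores hard disks.
Gaussian sensor noise (σ = 2 gray levels) is added last. All randomness
derives from the scene seed through two independent streams (vessel growth,
noise), so renders are bit-identical per (spec, seed) and the scene sampler
can place lesions clear of the vessel paths it knows deterministically.

Sampler defaults — 3–10 MAs of radius 3–12 px at contrast 40–80, 0–3
exudates — keep MA pixels below 1 % of the FOV. The recovery-study family
(`high_contrast_sampler`) narrows this to radius 6–12 px at contrast 60–90,
placed at least 10 px clear of anatomy: the regime in which a circle
detector with r ≥ 5 is expected to succeed. Lesion density and contrast in
real screening datasets are not published at this granularity; these
defaults are stand-ins chosen once, not calibrated to any clinical
collection.

**What passing tests show** — that every stage behaves per its contract and
that the integrated pipeline recovers circular, well-contrasted,
off-anatomy lesions with high sensitivity and precision under exact ground
truth. **What they do not show** — performance on real retinas, where
lesion shape is irregular, contrast is lower, anatomy overlaps lesions, and
acquisition artefacts abound; the generator has no texture, haemorrhages or
compression artefacts, and real-data figures reported for classical
pipelines are far below the synthetic figures here.

## Problem sizes

The recovery study and the acceptance run use 20 scenes at 768 × 576 — large
enough for stable rates (~150 lesions) while a full run stays around one to
two minutes on a single CPU. The Hough oracle equivalence check uses 50
64 × 64 maps, where exhaustive triple-loop voting is tractable.

## Known limitations

* The optic-disc radius estimate assumes an approximately isotropic bright
  region; a heavily occluded disc degrades to the range clip.
* The vessel detector misses vessels thinner than ~1 px after top-hat
  thresholding and may retain exudate rims when they are elongated.
* Detected radii are frequently 1 px under the nominal lesion radius
  because a soft-profiled lesion thresholds to a slightly smaller disk;
  centre-distance matching is insensitive to this.
* The box path trusts external confidences as given; no calibration is
  attempted.
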