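# Methods

## The annotation model

The annotator assumes each bounding box contains a single plant whose
foliage is chromatically separable from the background in hue, and that
the widest green band `H ∈ [22, 85]` (byte scale, half-degrees) is a
superset of the plant's hues. Background clutter that leaks into the wide
band — yellow-brown soil fringes, bright stones — is assumed to occupy the
*low* end of the band, so raising the lower hue bound one step at a time
sheds clutter before it sheds foliage. The scoring of the resulting mask
sequence then reduces mask selection to change-point detection: as long as
consecutive masks differ little, narrowing is removing nothing that
matters; the first large inter-iteration change marks the step where real
plant structure was lost, and the mask just before it is kept.

Two coefficients quantify "change". `k_area = S_i/S_{i-1}` is the pixel
area ratio of the principal connected component between consecutive
*stored* iterations (bands whose largest component falls below the
50-pixel floor are skipped and do not advance the predecessor, so the
ratio always compares two masks that actually exist; the first stored
iteration scores 1 by definition). `k_shape` is the area of the
component's tight bounding rectangle over the crop area: a thin leaf can
vanish while `k_area` barely moves, but the bounding rectangle contracts.
The integral score is the convex combination `w_area·k_area +
w_shape·k_shape` with default weights 0.7/0.3; the weight sweep in the
evaluation module re-runs the full pipeline for all eleven (w_area,
w_shape) pairs in steps of 0.1 so the trade-off can be measured rather
than asserted.

### The drop rule

"First significant drop" is operationalized as the first consecutive-pair
decrease exceeding `drop_fraction × (max − min)` of the stored scores
(default fraction 0.2, range over the whole history, not a running
prefix). The selected index is the record *before* that pair. When the
range is zero or no pair qualifies, the last stored record — the narrowest
band that stayed stable — is selected. An empty history (no band produced
a usable component, e.g. a box containing only soil) yields no annotation;
that is a value, not an error, and such boxes are skipped with a log line.

Two consequences of this rule are worth knowing. First, it is scale-free:
a history that only jitters near 1.0 has a tiny range, and a jitter-sized
dip can count as "significant". Degradation detection is therefore only as
good as the contrast between the plant-loss drop and the clutter-shedding
dips; nearly-flat histories select early. Second, because `k_area` is a
consecutive ratio, the score rebounds after every loss, so the score range
is set by the single worst step, not by cumulative decline.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `h_start`, `h_top` | 22, 85 | widest hue band, 0–179 byte scale |
| `n_bands` | 16 | iterations; band *i* is [h_start+i, h_top] |
| `s_bounds` | (20, 255) | saturation gate; excludes near-achromatic soil |
| `v_bounds` | (20, 240) | value gate; excludes deep shadow and blown highlights |
| `min_area` | 50 px | smallest component treated as an object |
| `w_area`, `w_shape` | 0.7, 0.3 | score weights (must sum to 1) |
| `drop_fraction` | 0.2 | significant-drop threshold, fraction of score range |
| `epsilon_factor` | 0.0015 | Douglas–Peucker tolerance, fraction of perimeter |

`n_bands = 16` keeps the narrowest band at [37, 85]. All parameters are
exposed in the CLI and in the YAML config (`annotator:` section).

## Implementation notes

Everything is built on scikit-image/scipy. HSV conversion is an own
vectorized routine pinned to the byte convention (H 0–179, S/V 0–255) the
band bounds are written in, cross-checked against `colorsys` in the tests.
Morphology uses 3×3 square structuring elements with the border treated as
each operation's identity (erosion sees foreground outside the frame,
dilation background), so a mask touching the crop edge is not eaten by the
closing step. Components are 8-connected; "contour area" is the component
pixel count and the contour rectangle is the component's tight pixel
bounding box; ties in the largest-component choice go to the first in
row-major scan order. The traced boundary (marching squares at level 0.5)
is what Douglas–Peucker simplifies; with tolerance 0 all points are kept,
and results with fewer than three vertices are rejected rather than
padded. Polygon vertices are clamped (not rejected) at image edges, since
field-image boxes routinely abut the frame. YOLO-seg lines are written
with 6-decimal fixed precision; parsing and denormalizing a line
reproduces the vertices within one-pixel quantization.

The baselines share one contract (crop → binary mask). Otsu and the
adaptive threshold binarize ITU-R 601 luminance and then take whichever
side of the binarization has mean hue closest to the green band center —
raw binarization has no notion of vegetation, and without this rule those
methods cannot emit a plant mask at all. A constant-luminance crop has no
contrast to threshold and returns an empty mask (logged) for both, the
same degenerate rule regardless of offset. K-means clusters in HSV with
hue embedded as a (cos, sin) pair to respect circularity, deterministic
under the configured seed, and selects the cluster with the greenest
centroid. Both-empty mask pairs in the metrics are defined as perfect
agreement (100) with a warning; the identity `DSC = 2·IoU/(1+IoU)` holds
per pair and is asserted in the tests, but not for averaged values.

## The synthetic scene generator

The generator stands in for field imagery so every stage has an exact
oracle. What it emulates: green leaf rosettes (a central disk plus 4–8
elongated elliptical lobes attached through the disk) with per-leaf hue
variation inside `plant_hue_range` (default [35, 75]); textured brown/grey
soil whose hues sit below the green band floor or fail the saturation
gate; multiplicative value-channel shadowing over one side of a rosette;
and bright, weakly saturated stones whose hue (23–34) sits just inside the
wide end of the detection band — placed partly *inside* plant bounding
boxes so a crop cannot exclude them. Stone hue ramps smoothly across each
blob, so narrowing sheds stones one slice per iteration (a gradual score
decline), while the rosette's central disk is painted at the extreme
yellow edge of the plant range and is lost in the final narrowing step in
one piece, disconnecting the rosette — the sharp drop that anchors the
score range. The interplay is deliberate: it reproduces, in miniature, the
trace shape the method is designed around (slow clutter shedding, then a
catastrophic structure loss), and it is what makes the iterative method
measurably better than the single-shot fixed band on hard scenes.

Scene colors are composed in HSV and converted to RGB once, with sampling
margins of one hue step so uint8 round-trip quantization cannot push a
plant pixel outside the configured range. Per-scene seeds derive from the
master seed; identical configs give byte-identical scenes.

What it does **not** emulate: perspective and scale variation, leaf
occlusion between plants, specular highlights, illumination gradients,
motion blur, real soil texture statistics, or plants whose hue overlaps
the clutter band. Passing the clean-scene recovery bound (mean IoU ≥ 90%
over 50 scenes) and the hard-scene ranking therefore demonstrates that the
pipeline is internally correct and that the score-based selection performs
its intended function — not that these accuracy numbers transfer to real
field imagery.

## Problem sizes

Default study conditions: 256×256 scenes, three plants each, rosette radii
9–15% of the scene side. Clean-scene and hard-scene evaluations use 50
scenes (150 objects); the weight sweep re-runs the annotator for eleven
weight pairs over 12 scenes. These sizes give stable means (the clean IoU
moves by well under a point between seed batches) while keeping a full
evaluation run under a minute on one CPU.

## Known limitations

* One polygon per box: the principal component only, no multi-object
  boxes, no holes.
* The drop rule's scale-freeness (see above) makes selection noisy when
  the score history is nearly flat; on clean scenes this is harmless
  because every stored mask is then nearly identical.
* Duplicate-box cleaning removes same-class boxes with IoU ≥ 0.9 only;
  mis-classified or oversized boxes are surfaced in the report but not
  corrected — those corrections need human judgment.
* No adaptive processing of the saturation/value channels; the S/V gates
  are fixed per run.
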