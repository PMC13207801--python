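# greenpoly

Automatic polygon annotation of plant objects in field-crop images.

Training instance-segmentation models (YOLO-seg and friends) for crop/weed
discrimination needs polygonal masks, but most agricultural datasets ship
only bounding boxes, and drawing polygons by hand is slow and subjective.
`greenpoly` turns each bounding box into a polygon automatically: it
segments the plant inside the box by adaptive color analysis in HSV space
and exports YOLO-seg label files, so a box-only dataset becomes a
segmentation dataset without an annotator in the loop.

## Method

Vegetation is chromatically compact: green foliage occupies a narrow hue
band while soil, stones and mulch sit outside it — but the *right* band
varies per image and per plant. For one crop (the pixels inside one box)
the algorithm sweeps a family of nested hue bands

    H ∈ [22 + i, 85],  i = 0 … 15   (hue on the 0–179 byte scale),
    S ∈ [20, 255],  V ∈ [20, 240]

thresholds the crop at each band, cleans the binary mask by morphological
closing (3×3, 2 iterations) then opening (3×3, 1 iteration), and keeps the
largest connected component (minimum 50 px). Each stored iteration *i* is
scored by an integral contour-quality metric

    k_area  = S_i / S_{i−1}                       (area-change ratio)
    k_shape = (W_contour · H_contour) / (W · H)   (bounding-rect ratio)
    Score   = w_area · k_area + w_shape · k_shape,   w = (0.7, 0.3)

`k_area` collapses when a large part of the object is lost between
consecutive bands; `k_shape` catches the loss of elongated leaves that
barely change total area but shrink the contour's bounding rectangle. The
mask kept is the one from the **last stable iteration before the first
significant drop** in Score (a consecutive decrease exceeding 20% of the
observed score range); if no drop occurs the narrowest stable band wins.
The winning contour is simplified with Douglas–Peucker
(ε = 0.0015 × perimeter), mapped back to image coordinates and written as
a normalized YOLO-seg polygon line.

The package also ships the surrounding machinery: a Pascal VOC reader with
duplicate-box cleaning, IoU/Dice mask evaluation, a score-weight sweep,
four classical baselines (fixed HSV threshold, Otsu, adaptive threshold,
K-means) for comparison, and a seeded synthetic-scene generator that
renders field-like images (leaf rosettes on textured soil, shadows, bright
stones) with exact ground-truth masks, so the whole pipeline is testable
offline.

## Worked example

```
$ greenpoly synth --n 5 --seed 7 --out field --shadow-strength 0.5 --stone-probability 0.7
wrote 5 scenes to field

$ greenpoly annotate --in field --out annotated
wrote labels for 15 objects to annotated/labels

$ greenpoly evaluate --in field --labels annotated/labels --out eval.csv
overall IoU 93.41% DSC 96.58% (15 objects)
```

The first command renders five 256×256 synthetic field scenes (three
plants each) with shadowing and stone artifacts, writing PNG images,
Pascal VOC XML boxes and reference masks. The second converts every box
into a polygon label; `annotated/labels/scene_0000.txt` holds one line per
object — class id (0 = crop, 1 = weed) followed by the normalized polygon:

```
0 0.605469 0.755859 0.591797 0.753906 0.591797 0.746094 0.583984 ...
```

The third scores the emitted polygons against the generator's ground
truth: a mean intersection-over-union of 93.41% and Dice coefficient of
96.58% over the 15 objects, i.e. the automatic polygons recover almost all
of each plant despite the shadows and the in-band stone clutter. Per-image
rows are written to `eval.csv`. `greenpoly baseline --method fixed_hsv ...`
runs one of the classical comparison segmenters through the same export
path, and `greenpoly sweep` re-runs the annotator over the 11-pair
score-weight grid and writes the quality table as CSV.

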