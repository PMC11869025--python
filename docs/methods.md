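# Methods

## The detection model

`vinescout` treats grape-bunch counting as tiled instance segmentation
constrained to the foreground vine row. The pipeline assumes row-
structured imagery, as produced by photographing a vertically trellised
vineyard from the inter-row corridor: one in-focus row fills a horizontal
band of the frame and everything else (sky, ground, further rows) is
visually distinct. Stage 1 produces a boolean foreground mask; stages
2–3 are deterministic geometry (zone extraction, overlap patching);
stage 4 produces scored polygons per patch; stage 5 reassembles and
counts.

Two design questions were genuinely open and are resolved as follows.

**Instance identity through reassembly.** Stage 5 could produce only a
semantic mask, but counting needs instances, so instance identity is
retained through the merge. De-duplication builds a graph over
rasterized detection masks with an edge when IoU ≥ `merge_iou` (default
0.3) **or** when the intersection covers ≥ `containment` (default 0.8)
of the smaller mask; connected components become single instances. The
containment clause is what handles a bunch clipped at a patch seam: its
fragment has low IoU against the full detection from the neighbouring
patch but is almost entirely contained in it. Merged confidence is the
maximum over members. Raising `merge_iou` removes edges only, so the
count is monotone non-decreasing in the threshold.

**Foreground gating.** The stage-1 mask is applied as a hard gate, not a
soft prior: a detection with less than `foreground_gate` (default 0.5)
of its mask area inside the foreground is discarded. This reproduces the
intended behaviour that only the first row is ever counted, at the cost
of dropping genuine bunches in badly under-segmented foregrounds.

**Patch geometry.** Patches are 640 px squares with 128 px (20 %)
overlap by default. 640 matches the native input size of common
segmentation detectors; the overlap must exceed the largest bunch
diameter so that every bunch appears *whole* in at least one patch —
under that condition the reassembled count and fused mask are exactly
the ground truth (verified bit-exactly in the tests). Zones smaller than
the patch are reflect-padded rather than upscaled, preserving pixel
scale; detections falling in the padded margin are clipped away.

**Rasterization convention.** One convention is used everywhere: x =
column, y = row, origin top-left, rectangles half-open, and a pixel
belongs to a polygon iff its center lies strictly inside. With integer-
edged rectangles and half-integer centers this is exact (an integer
a×b rectangle rasterizes to exactly a·b pixels), which is what makes the
patch round-trip and the polygon-vs-pixel-count IoU identities testable
to machine precision rather than approximately.

## Backends

The two neural stages are contracts, not bundled networks — field-scale
referring-segmentation and instance-segmentation models need GPUs and
weights that have no place in a desk-testable package. Reference
implementations exist for both:

- *Foreground*: Otsu threshold on luminance, hole filling (dark bunches
  punch holes in a bright canopy), then retention of the dominant
  contiguous bright band — components whose row extent overlaps the
  largest component's rows and whose area is ≥ 5 % of it. A second
  bright band elsewhere (a background row) is discarded.
- *Instances*: HSV hue window (default 0.60–0.85, the blue-purple of
  bunch pixels, disjoint from foliage greens), saturation/value floors,
  morphological closing, connected components with a 30 px area floor,
  and largest-contour extraction. Confidence is component area divided
  by bounding-box area — a convexity proxy. This definition is invented;
  any monotone score serves, because evaluation consumes only a ranking.

Contours are extracted by marching squares and Douglas–Peucker
simplified at 1 px; the simplification tolerance is halved automatically
until the polygon area is preserved to 0.5 %, since a fixed tolerance
bites visibly into small shapes.

## The synthetic scene generator

The generator emulates the features the pipeline actually keys on: a
bright sharp foreground band (canopy green, heavy texture noise), dim
Gaussian-blurred background rows, elliptical bunches (taller than wide,
pairwise disjoint by rejection sampling, ≥ 4 px apart) in a hue band
separable from foliage, and leaf-colored occluders. It does **not**
emulate photorealism: no berry texture, no partial occlusion rendering,
no specular highlights, no perspective, single-sided imaging only.
Passing tests therefore demonstrate the correctness of the pipeline
*machinery* — geometry, merging, counting, gating, metrics — not the
accuracy of any neural backend on real imagery, where precision and
recall will be materially lower.

Occlusion is whole-bunch: each bunch is hidden with probability
`occlusion_fraction` (default 0.2, the rate observed in untrimmed
commercial canopies) by drawing a slightly dilated leaf-colored ellipse
over it, and hidden bunches are excluded from `visible_instances`.
Count-based occlusion statistics are then exact by construction:
`gt − visible = occluded`.

Per-plant bunch counts default to a negative binomial with mean 10.7
(the per-plant average of the field survey scale the package models:
449 bunches over 42 plants) and dispersion k = 4. Field counts are
overdispersed relative to Poisson — vigour, disease and pruning vary
between plants — and the regression-based validation needs realistic
between-plant spread to be meaningful; Poisson and fixed counts remain
available through `ClusterCountModel`. Each scene draws from a stream
seeded by `(seed, scene_index)`, so plot generation is order-independent
and reproducible bit for bit.

Trunks sit on the planting grid of the modelled vineyards: 2.5 m between
plants along a row, 3 m between rows, coordinates in ETRS89 / UTM 29N.

## Labels

MOTS annotations use the column-major compressed run-length string
format (5-bit little-endian groups, delta-coded counts, printable-ASCII
packing); the codec here is written from scratch and tested against an
independent decoder plus hand-built fixtures. Two YOLO-seg label
dialects are emitted — `<class> <cx> <cy> <w> <h> <x1> <y1> …` with a
normalized tight bounding box, and the common class+polygon form —
because downstream tooling disagrees on the layout. Grayscale
"adjustment" is implemented as a percentile contrast stretch (defaults
1/99) applied through a single luminance-derived linear map so hue is
preserved. Patch-split labels drop clipped pieces below 10 % of the
original instance area (slivers teach a detector nothing). Augmentation
covers horizontal/vertical flips, quarter-turn rotations and isotropic
scaling, applied identically to pixels and polygons; the train/val split
shuffles *groups* (source videos), never frames, so no sequence spans
the split.

## Metrics

Matching is greedy by descending confidence with ties broken by best
available IoU and then input order; each prediction claims the unmatched
ground-truth instance of highest IoU ≥ 0.5. For disjoint ground-truth
instances at threshold 0.5 a prediction can clear the threshold against
at most one of them, so greedy matching attains the optimal TP count —
the tests verify this against maximum bipartite matching. AP uses
all-point interpolation (the precision envelope integrated over recall
increments at every distinct confidence), matching modern detector
tooling; the test oracle recomputes it by brute-force threshold
enumeration with Hungarian matching. IoU is computed on rasterized
masks, not boxes, because the evaluated object is the segmentation
polygon; box IoU is available behind a flag. Undefined metrics (no
predictions, empty ground truth) surface as NaN or an exception, never a
silent zero.

## Yield mapping

IDW with power p = 2 over the k = 12 nearest populated plants on a 1 m
grid, defaults chosen from common geostatistical practice and all
configurable; the survey design prescribes none of them. Cell centers
within 1e-9 m of a plant take that plant's count exactly (averaged over
coincident plants), which gives exact interpolation without dividing by
zero. Interpolated values are convex combinations of neighbour counts,
hence bounded by their range, and a constant field is preserved.
Replant-flagged plants (young vines not in full production) are excluded
at the join stage. The module checks that all inputs share one CRS and
never reprojects — coordinate conversion is the caller's job. Rasters
export as ESRI ASCII grids (row 0 = north), points as CSV and GeoJSON.

## Validation statistics

Method pairs (field count vs visual count vs pipeline count) are
compared by OLS with intercept *and* by the through-origin slope
Σxy/Σx², because count scatter is naturally anchored at the origin and
the through-origin slope reads directly as an undercount fraction. RMSE
is taken on direct differences y − x (inter-method disagreement in
bunches); the OLS-residual RMSE is reported separately as `fit_rmse`.
The group tests use Welch's unequal-variance t-test, two-sided — the
safer default when group variances are unknown; with zero variance in
both groups the convention is p = 1 for equal means. Raw p-values are
reported without multiple-testing correction (three planned contrasts),
and interpretation is left to the caller. The null-uniformity check in
the test suite uses groups of 20 and 25 with unequal variances; at much
smaller sizes the Welch–Satterthwaite approximation itself is visibly
inexact, which is a property of the test, not of this implementation.

## Problem sizes and numerical choices

The shipped tests run the full pipeline on 20 scenes of 800×600 px and
the bit-exact reassembly check on 50 scenes; the acceptance script uses
a 20-plant plot, 500 regression replicates and 2000 null t-tests. These
sizes give sampling errors comfortably inside the tolerances asserted
(e.g. the occlusion-rate standard error at ~200 bunches is ~0.03 against
a ±0.05 band) while keeping a full run in tens of seconds on one core.
Degenerate inputs are defined, not improvised: empty masks yield empty
zone lists, a constant image is returned unchanged by the contrast
stretch, an empty match table raises rather than scoring 0, and IoU of
two empty masks is an error unless explicitly flagged as 1.

## Known limitations

- The reference backends are calibrated to the synthetic palette; they
  are stand-ins for neural models, not field-ready detectors.
- Whole-bunch occlusion ignores partially hidden bunches, which real
  detectors find at reduced confidence; count-based occlusion statistics
  are unaffected but PR curves on real data will differ in shape.
- Bunches never overlap in synthetic scenes, so the merge rule is not
  stressed by genuinely touching instances (where any count-preserving
  merge rule is ill-posed without appearance cues).
- Yield surfaces interpolate bunch *counts*; converting to mass requires
  a bunch-weight model out of scope here.
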