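# Methods

## Problem setting

Routine diatom analysis images whole microscope slides at high magnification,
producing gigapixel "virtual slides" (on the order of 55,000 × 39,000 px at
~0.09 µm/px) in 8-bit bright-field grayscale. Relevant objects — diatom
valves and frustules that are at least about 75% complete — are sparse and
surrounded by clutter: small valve fragments, thin girdle bands, and
non-diatom debris such as silt or clay. Segmentation models consume fixed
512 × 512 px inputs, so both training-data preparation and slide-scale
inference reduce to tiling questions. This package implements the tiling
side of that problem: how tiles are positioned relative to annotated
objects, which objects enter a tile's ground-truth mask, and how per-tile
predictions are reassembled and scored at slide scale.

## Tiling schemes

All schemes emit exactly `tile_size × tile_size` tiles (default 512) that
lie fully inside the region; training tiles are clamped at borders, never
padded.

**Fixed-stride.** A sliding-window grid with stride 256 px, i.e. 50%
overlap with each horizontal and vertical neighbor, so every interior pixel
(and hence every small interior object) is covered by exactly
`(tile_size / stride)² = 4` tiles. When the region extent is not a stride
multiple, one extra origin clamped to `extent − tile_size` is appended per
axis so coverage is complete. The tile mask is simply the slide-level
binary mask restricted to the window: objects are truncated arbitrarily by
tile borders.

**Object-based positioning.** Nine tiles per annotated object, justifying
the object's bounding box horizontally to left/center/right and vertically
to top/center/bottom, with a 10 px margin between box and tile boundary on
the justified sides. Center justification distributes the slack with floor
rounding of the top/left offset. Origins are clamped into the region, so
near a slide border several justifications may coincide; all nine tiles are
still emitted (their provenance distinguishes them), and an opt-in `dedupe`
flag drops coincident duplicates for callers that want unique windows.
Neighboring objects falling inside a tile by proximity are included in its
mask.

**Object integrity constraint (OIC).** Tile positions are identical to
object-based positioning, but an object enters the mask only if at least
75% of its pixel-counted area lies inside the tile. Objects whose bounding
box is taller or wider than the tile would essentially always fail that
rule, so they are instead included when they occupy (≥ 1 pixel) at least
two of the tile's four midline quadrants. The rule is applied uniformly to
every instance including the anchor: a non-oversize anchor is fully
contained by construction and always passes, so uniformity changes nothing
for it while keeping the implementation rule-driven rather than
case-driven. Setting the threshold to 0 disables the constraint and
recovers the plain object-based mask exactly. Excluded objects remain
visible in the image patch — only the mask is rewritten, which is the
point: substantially cropped valves resemble the small fragments that a
diatom count would ignore, and the mask should say so.

**Empty-tile filtering.** Tiles with empty masks are removed from training
and validation sets (the removed fraction is reported; on sparse real
slides it is large). At evaluation, empty tiles are retained, since object
positions are unknown in production.

## Partitioning and subsets

The annotated rectangle is split into contiguous train/validation/
evaluation strips (default fractions 0.6/0.2/0.2 along rows) using a
cumulative-floor rule: boundary *k* sits at `floor(cumsum(fractions)[k] ×
extent)`, so realized areas deviate from targets by at most one line.
Objects straddling strip boundaries are assigned to the strip holding the
majority of their pixels, ties toward the earlier strip in train <
validation < evaluation order; the stored mask is then clipped to the strip.
The source data does not record how straddlers were handled; majority
assignment is this package's choice and is the one the tests encode.

Training subsets (10/25/50/100% of objects) are produced by horizontally
clipping the training strip at the leftmost column whose majority-contained
object count first reaches `ceil(fraction × total)`.

## Evaluation pipeline

Evaluation tiling extends the fixed-stride grid by one stride before each
region edge (origins start at −256), and fills out-of-region pixels by
mirror reflection about the boundary with half-sample symmetry — the padded
pixel at column −1 equals the region pixel at column 0 (`numpy.pad
mode='symmetric'`). This makes every region pixel, border pixels included,
covered by exactly four tiles.

Backends plug in through a `TileSegmenter` contract: a callable from (tile
image patch, tile origin) to either a tile-shaped score matrix or a list of
per-instance predictions (binary mask + scalar score). Instance predictions
are fused into a score matrix by per-pixel maximum over the instances
covering a pixel, zero elsewhere; the source does not state how overlapping
instance scores were reduced within a tile, and max was chosen for
consistency with the cross-tile rule. Tile scores are stitched to slide
scale by per-pixel maximum over the four covering tiles (padded margins
cropped), then thresholded at 0.90/0.95/0.98 with an inclusive ≥
comparison. Max-stitching commutes with thresholding
(`threshold(max-stitch) = OR-stitch(threshold)`), which the tests verify,
and is order-independent.

An `oracle_segmenter` stands in for trained models in tests and pipelines:
`none` scores ground-truth pixels 1.0 (the full pipeline must then return
Dice = precision = recall = 1 at any threshold ≤ 1 — any deviation is a
tiling/stitching bug); `boundary_erosion` erodes the mask by k px (recall
falls with k, precision stays 1); `score_jitter` subtracts |N(0, sd)| from
foreground scores, seeded per tile origin for reproducibility.

## Metrics and effects model

Pixel confusion counts are exact integers; precision = TP/(TP+FP), recall =
TP/(TP+FN), Dice = 2TP/(2TP+FP+FN). A zero denominator yields an explicit
undefined flag (`None`), never a sentinel 0 or 1; aggregation skips flagged
values and reports how many were skipped, to avoid silently biased means.
Jaccard is deliberately omitted as a monotone transform of Dice.

Factor effects over the factorial grid (tiling method × subset size ×
threshold, replicated over slides) are fit by OLS on an additive model with
treatment coding against the baseline cell (fixed stride, 10%, 0.90). The
intercept is the fitted baseline-cell value; coefficients are level deltas
with t-based two-sided p-values, reported descriptively without
multiple-testing correction. The fit uses one record per slide × cell
(slides weighted equally), not pooled pixels. On noise-free additive data
the coefficients are recovered to numerical precision (~1e-16), and with
noise they match an explicit normal-equations solve.

## Synthetic slides

The generator renders desk-scale stand-ins for annotated virtual slides:
a uniform bright background (default level 220) with Gaussian noise (sd 6),
dark elongated objects (ellipses and capsules, length 80–260 px, aspect
1.2–4, gray 40–140, optional periodic striation), and three distractor
classes — fragments made by cutting a full shape with a random chord that
retains 30–70% of its area (below the 75% integrity threshold by
construction), thin arc "bands", and lobed debris blobs. Shapes are placed
by rejection sampling so instance masks are pairwise disjoint at default
settings; placement failure on an overcrowded config raises rather than
silently dropping annotated objects (distractors are best-effort). Defaults
produce a 2048 × 2048 slide with 12 objects, 6 fragments, 10 debris blobs
and 4 bands — sparse enough that a sizable share of fixed-stride tiles is
empty, mirroring the class imbalance the empty-tile filter exists for.

What the generator does **not** emulate: focus-stacking artifacts,
illumination structure beyond an optional linear gradient, dense
aggregates, touching/overlapping cells, taxonomic shape diversity, and
realistic texture. Passing tests therefore demonstrate the correctness of
the tiling/stitching/metric machinery, not segmentation difficulty of real
material; the empty-tile fractions and metric values obtained on synthetic
slides are properties of these synthetic conditions.

## Numerical choices

- Coordinates are 0-based, half-open `[r0, r1) × [c0, c1)` everywhere.
- Areas are exact pixel counts; the integrity fraction is
  `pixels_inside / pixels_total` compared with ≥.
- Quadrant occupancy requires ≥ 1 pixel (no fraction is defined for it).
- COCO export traces each 8-connected mask component with marching squares
  at level 0.5 (pixel centers at half-integer coordinates); holes become
  additional polygons with even-odd semantics. Import rasterizes polygons
  by point-in-polygon tests on pixel centers, XOR-combining polygons within
  an annotation. Round trips preserve component counts exactly and
  per-component Dice ≥ 0.99 (in practice 1.0 on generated shapes).
- All generator randomness flows from `numpy.random.default_rng(seed)`;
  jitter sub-seeds derive from (seed, tile origin) so tile order is
  irrelevant.

## Problem sizes

Tests and the acceptance script run on slides between 900 × 1100 and
3072 × 3072 px with 1–20 objects, chosen as the smallest sizes at which
every geometric regime appears (interior and border tiles, clamped
justifications, oversize objects, multi-tile coverage). The structural
quantities they measure — tiles per object, overlap fraction, coverage
multiplicity, recovered threshold, margins, partition split — are
size-invariant by construction, so desk-scale slides exercise them fully.

## Known limitations

- Stitching merges overlapping detections; instance identity is not
  preserved across tiles (object-level metrics such as AP are out of
  scope).
- The CLI's `evaluate` covers the stitching stage end to end; there is no
  standalone `stitch` command because no on-disk interchange format for
  per-tile score stacks is defined.
- `clip_training_subset` clips strictly from the left, matching the
  horizontal-clipping protocol; other clip directions are not implemented.
- Training and evaluation assume one positive class ("diatom"); the data
  model has no multi-class ontology.
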