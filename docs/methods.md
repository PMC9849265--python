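# Methods

This note records the procedures, conventions, and parameter choices behind
`mosaicount`, and what its synthetic tests do and do not demonstrate about
real survey imagery.

## Coordinates and annotation files

All coordinates are integer pixels with origin at the mosaic's top-left and
half-open boxes `[x0, x1) × [y0, y1)`. The half-open convention makes areas,
intersections, and tile arithmetic exact in integers; there is no
georeferencing anywhere in the package. Annotation files are headered CSV
(`mosaic_id,label,x0,y0,x1,y1,confidence`), one box per row, UTF-8; the
label vocabulary is closed (`adult`, `calf`, `ghost`; the long
"… caribou" phrases are normalized on read) and anything else is rejected
rather than coerced. Confidence is blank for human annotations and a
`[0, 1]` value for detector output, written to 6 decimals. Writing then
reading a set is the identity.

## Tiling geometry

Tiles are `tile_size` (default 1000 px) squares starting at multiples of
`stride = tile_size − overlap` (default overlap 100 px → stride 900). The
per-axis tile count is the smallest whose extents cover the axis,
`max(1, ceil((dim − overlap) / stride))`; the final row/column is clipped to
the mosaic rather than padded (padding is a rendering concern, not a
geometry concern). Each tile's *core* is the `[i·stride, (i+1)·stride)` band,
except that the last tile's core extends to the mosaic edge; cores therefore
partition the mosaic exactly while extents overlap.

Ownership is by top-left corner: an annotation belongs to the tile whose core
contains `(x0, y0)`, with the index clamped to the last tile. Any box with
both sides ≤ the overlap is then guaranteed to lie fully inside its owner's
extent. Larger boxes are kept, unclipped, with a logged warning — they can
overhang the owner tile. Merging per-tile detections keeps a detection only
if the emitting tile owns it, which makes assign → report → merge the
identity (verified on randomized mosaics); optional per-label NMS then
suppresses same-label pairs above an IoU threshold, keeping the
highest-confidence box.

One practical asymmetry surfaced during development: a detector sees animal
*fragments* clipped at a tile's leading (left/top) edge, whose clipped
top-left corner falls exactly at the emitting tile's core start, so the owner
rule alone would keep them as spurious boxes. The baseline detector therefore
drops detections within 3 px of a leading tile edge whenever a neighbour
exists in that direction (3 px because the morphological opening erodes
clipped fragments slightly off the edge). The cost is that an animal whose
box starts within 3 px of a core boundary can be lost (probability of order
3/stride per animal per axis); the benefit is that duplicated fragments never
survive. The tiling module itself stays a pure owner rule so the
count-conservation invariant is exact.

Train/test tile splits are seeded and, by default, stratified per mosaic
(each mosaic contributes `round(fraction · n_tiles)` training tiles, ties
rounding up), since per-mosaic tile counts are the reporting unit of the
workflow this mirrors. Tiles without annotations participate normally —
empty tiles are negative examples.

## Matching and counting

The matching criterion between a compared set and the reference is greedy
one-to-one: all cross pairs with IoU ≥ the threshold, visited in descending
IoU (ties: smaller center distance, then lower reference index, then lower
predicted index), each box used at most once. The default threshold is 0.3 —
deliberately loose, because human boxes around the same animal vary and
overlapping adult/ghost detections occur; it is a configuration knob, not a
claim. Matching is label-blind by default; label agreement is settled when
counts are derived:

* pooled ("species") level: every matched pair is a TP, every unmatched
  prediction an FP, every unmatched reference an FN;
* per class: a label-mismatched pair contributes an FP to the predicted
  class *and* an FN to the reference class. This convention reproduces the
  published per-class tallies this package's report tables mirror, and keeps
  `TP_pooled + FN_pooled = |reference|` and `TP_pooled + FP_pooled =
  |predicted|` exact.

A confusion table cross-classifies the same events (reference class ×
predicted outcome, with an `object` row for spurious predictions and a
`missed` column), so each reference row sums to that class's reference
count. Greedy matching can in principle fall short of a maximum bipartite
matching; tests check it never exceeds the brute-force optimum and equals it
whenever no box overlaps more than one candidate above threshold — the
regime survey scenes with separated animals live in.

## Metrics and reporting

`accuracy = TP/(TP+FP+FN)` (the detection community's critical success
index — no true negatives), `precision = TP/(TP+FP)`,
`recall = TP/(TP+FN)`. Zero denominators raise an explicit
undefined-metric error; reports show blanks, never silent zeros or NaN.
Percentage difference of raw counts has two documented denominator
conventions — reference count (default) and test count — because published
comparison tables use both in different places; the choice is a parameter.
The misclassification proportion for "class y annotated as x" is
`n / (n + TP_x)`, the convention that reproduces the published
misclassification tables. Raw values are always retained; report formatting
rounds half-up (ties away from zero) to 2 decimals for proportions and 1 for
percentages, matching hand-formatted tables rather than banker's rounding.
Per-tile Pearson correlations use the sample coefficient and require length
≥ 3 with non-zero variance.

Observer pooling reports mean ± sample SD (ddof = 1; a single observer gets
SD 0) per cell, and *also* recomputes metrics from the pooled mean counts:
"mean of metrics" and "metrics of mean counts" differ, published aggregate
rows follow the latter, and both are emitted with labels.

## Synthetic scenes and simulated observers

The generator reproduces the statistical structure the analysis depends on,
not photographic realism. Background is a sum of seeded Gaussian random
fields (broad meadow tones, mid-scale texture, fine grain) with darker
shrub/water patches. Animals are soft-edged elongated blobs brighter than
background; adult body length is drawn from 1.3–2.1 m and converted to
pixels via the ground sampling distance (presets 2.4 cm/px and 3.7 cm/px,
the two flight altitudes of the reference survey design), calves at 0.5–0.7
of adult length. Ghosts are the same sprites Gaussian-blurred (σ 1–3 px) and
composited at opacity 0.25–0.6 — measurably lower-contrast than adults,
which is the property that makes them a hard class. These numeric ranges are
package defaults chosen to be field-plausible; no survey publishes them.
Truth boxes are the tight bounding box of composited sprite pixels
(opacity > 0.05). Placement is rejection sampling with a minimum center
separation (default 50 px) and bounded retries; infeasible requests raise a
capacity error reporting what was placed. Distractors (rocks, birds, trunks)
are rendered into the raster but kept out of the truth set.

A simulated observer makes one categorical draw per true animal: miss with
`miss_prob[class]`, otherwise label by the class's confusion row (the row
plus the miss probability must sum to 1), then jitter box corners with
normal noise. Spurious detections are placed on distractors at a configured
rate per 100 distractors — zero for human-like observers, reflecting that
people do not mark rocks as animals while detectors do. Detector-like
annotators draw Beta-distributed confidences (needed to exercise NMS).
Scene and observers use separate seeded streams so observers can be
re-simulated without re-rendering. Observer errors are independent across
animals and observers; real observers err on the *same* hard individuals,
so inter-observer correlation is not modeled and pooled-SD realism is
limited accordingly.

The fixture suite renders four scenes (two per GSD preset, echoing two
mosaics per altitude) with truth, a zero-error expert-like reference, five
naive-like observers (miss rates 0.05/0.07/0.20 for adult/calf/ghost, small
confusion rates, 2 px jitter), and a detector-like source (ghost miss 0.45,
object false positives, confidences), plus a manifest of every parameter.
Byte-for-byte reproducible given the seed.

## Baseline detector

The built-in detector exists to run the pipeline without trained weights; it
is not a learned model and its scores are not comparable to a CNN's.
Background is a rank-median filter (window 75 px — wide enough that an adult
sprite never dominates the window's median); foreground is the positive
residual above `z · σ` where σ is the robust (MAD) residual scale, z = 3.5
by default. Components pass a metric area gate (0.10–5.0 m², GSD-scaled),
are labeled calf below 0.55 m² and adult above, and are relabeled ghost when
mean contrast falls below 0.22 of full scale; confidence is normalized
contrast. Calf/adult sizes genuinely overlap (a large calf outsizes a small
adult), so area alone cannot separate them perfectly — as in real imagery.
Ghosts at the faint end of the opacity range sit at the detector's noise
floor (≈ 2 robust SDs) and are often missed at the default threshold; the
ghost detection test plants a mid-opacity ghost with a matched, lower
threshold. On easy scenes (sparse high-contrast adults, no ghosts or
distractors) the detector clears pooled precision and recall 0.95 — a smoke
floor for the pipeline, not a performance claim about any real detector.

## Problem sizes and determinism

Tests and the acceptance script are sized for a single CPU: scenes of
roughly 2400 × 1800 px (a 3 × 2 tile grid, so every overlap/ownership path
is exercised), observer-recovery runs of 500 planted animals over 100–200
seeds (binomial SE of the recovered miss rate ≈ 0.001, against a 3-SE
acceptance band), 500–1000 randomized instances for the matching and tiling
property suites. Every random draw flows from an explicit seed through
`numpy.random.default_rng`; scene rasters are bit-reproducible and all
simulations repeat exactly under the same seed.

## Known limitations

* No georeferencing, no photogrammetric ghost physics, no N-mixture or
  detection-probability modeling — counts are raw tallies.
* The synthetic background has no vegetation mimicking animal shapes and
  color; real false-positive structure will be richer.
* Greedy matching is a convention, not an inference about what human
  evaluators did; the IoU threshold is exposed for sensitivity analysis.
* Boxes larger than the tile overlap can overhang their owner tile; they are
  preserved but a detector working tile-by-tile may fragment them.
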