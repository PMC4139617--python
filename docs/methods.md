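# Methods

This note records the model behind `clumpsplit`, the parameters that
matter, the numerical choices made where the design was genuinely
open, what the synthetic scenes do and do not emulate, and the known
limitations.  All quantitative statements here are computed by the
test suite or by `scripts/acceptance.py`.

## Model and assumptions

The package treats a segmented histology image as a binary mask and a
cell as a roughly round, roughly convex foreground region.  Everything
follows from two assumptions:

1. **Within one image, cells are morphologically homogeneous**: one
   characteristic size and a round shape.  A clump of overlapping
   cells is then *larger* than the image-average object, *elongated*
   (low minor/major diameter ratio), and *more concave* (its convex
   hull bridges the pinch between member cells).  The stage-1 label
   chain — area above the image mean, then diameter-equality rescue at
   `gamma`, then concavity above the image mean — is exactly this
   argument run in sequence.  It fails by construction on images
   mixing very different cell sizes; that is a property of the method,
   not of the implementation.
2. **A pinch between overlapped cells leaves a concave deficit**: a
   connected component of hull-minus-cell (a "splitting triangle").
   The deepest arc point of each deficit marks where a pathologist
   would start the separating stroke, and a straight-ish cut between
   two such points across the neck severs the clump.

All geometry is pixel-set arithmetic: distances are chessboard
(Chebyshev) metric throughout — for morphological work on rasters it
behaves like the Euclidean metric at a fraction of the cost — with one
deliberate exception noted under *Pairing*.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `gamma` | 0.9 | – | diameter-equality threshold above which a large object counts as round (single) |
| `opening_radius` | 2 | px | disc structuring element removing noise specks |
| `closing_radius` | 2 | px | disc structuring element smoothing the contour |
| `min_st_area` | 5 | px | minimum hull-deficit component that counts as a dominant concave region |
| `min_fragment_frac` | 0.1 | of clump area | smallest fragment a cut may produce |
| `iou_threshold` | 0.5 | – | overlap needed to match a predicted cell to a true cell |

`gamma = 0.9` and the size-2 opening element are the method's
published operating point and are left untouched.  The closing uses
the same size-2 disc as the opening (the natural reading of a
procedure that names one element size); the radius is exposed because
closing trades contour smoothing against erosion of exactly the pinch
signal stage 2 reads.  Hole filling precedes opening precedes closing.

`min_st_area = 5` was chosen from raster measurements at the working
scale (512×512 masks, cell radii 8–14 px): with pixel-centre hulls,
contour rasterisation produces deficit slivers of 1–2 px while genuine
pinch deficits of even shallow overlaps measure 6 px and more, so 5
separates the two populations with margin on both sides.

## Numerical and geometric choices

- **Connectivity.** Foreground objects are 8-connected.  Cut paths are
  8-connected one-pixel curves, so fragments after cutting are counted
  with 4-connectivity — the digital-topology dual under which an
  8-curve separates its complement.  A 1-px 8-path does *not*
  8-disconnect its two sides across diagonal steps; the dual count is
  what makes "remove the path, count the pieces" correct.
- **Convex hulls** are filled polygons of the *pixel centres*
  (`convex_hull_image(..., offset_coordinates=False)`).  Corner-offset
  rasterisation inflates the hull of a small disc enough to fake a
  concavity of 0.05–0.07 on perfectly convex cells, destroying the
  contrast the concavity rule needs; with centre coordinates a
  rasterised disc has deficit 0.
- **Diameters.** The major diameter is the maximum Feret diameter of
  the pixel set (largest pairwise centre distance, attained on hull
  vertices); the minor diameter is the minimum caliper width (smallest
  hull extent over all directions, rotating-calipers).  This pair
  makes a disc score 1, a 2:1 rectangle ≈ 0.45 and a square ≈ 0.71.
  A single-pixel object is defined round (DE = 1) with a warning.
- **Edge/chord/arc.** The edge of a splitting triangle is its
  8-connected inner boundary (on binary regions this equals the
  gradient contour, deterministically).  The chord is the exact
  intersection of the edge with the hull contour; the arc is the rest.
  A tolerance band around the hull was tried and rejected: it swallows
  the whole edge of shallow 2-px-deep deficits, leaving no arc at all.
- **Splitting points.** Distance fields grown from the arc (DA) and
  the chord (DC) are summed; on the arc DA is 0, so the arc pixels
  maximising the sum are the pixels farthest from the chord.  Fields
  are grown per triangle over its own padded window — identical on the
  triangle's arc to the global-matrix formulation, and much cheaper.
  Because one deficit component can span *two* pinches of a chain
  clump (the hull bridges both on the same side), every local peak
  plateau of the chord-distance profile along the ordered arc becomes
  a *candidate* splitting point, the global maximum always included.
  Spurious rasterisation peaks are cheap: route validation (below)
  rejects the cuts they would induce.
- **Pairing.** Candidate pairs of splitting points are ranked by
  ascending *Euclidean* set distance; two points of the same concave
  region are never paired (a cut joins a concave region to its
  counterpart).  The chessboard metric is kept for all field growing
  and routing, but for ranking it under-measures diagonal separations
  by up to √2, which can prefer a diagonal slice through the cell body
  over the true across-neck pair in bent chains.
- **Route validation.** A candidate cut (geodesic corridor between the
  pair, thinned to one pixel) is accepted only if, applied to the
  clump's current region, it raises the 4-connected fragment count by
  exactly one and leaves every fragment at least `min_fragment_frac`
  of the clump area.  This sequential check eliminates the observed
  over-segmentation modes — corner nicks that sever nothing, shoulder
  slices between same-side pinches, crossing redundant routes — while
  leaving genuine across-neck cuts untouched.
- **Odd points / single concave region.** A point left unpaired falls
  back to contour partners: boundary pixels excluding anything within
  one chessboard pixel of any arc, clustered by distance tier, tried
  nearest-first under the same validation (up to 40 clusters).
  Fallback is skipped for points whose concave region already
  participates in an accepted cut — such extra peaks are artifacts.
- **Thinning** is the two-subiteration parallel scheme (Guo–Hall),
  implemented in-package so the two route endpoints can be anchored
  against deletion; it reduces width, never length.  On anchor-free
  shapes it is bit-identical to `skimage.morphology.thin`, which the
  tests use as the independent reference.  The final path is read off
  the skeleton as the breadth-first shortest path between the two
  anchors, which prunes any residual spur and guarantees a simple
  path: interior pixels have exactly two path neighbours.
- **Tie-breaking** is lexicographic (row, then column) everywhere —
  point anchors, pairing order, fallback clusters — so a run is a pure
  function of the input mask and configuration.
- **Degenerate inputs.** Empty masks yield empty object lists and
  count 0; a convex OC object (no deficit) or one whose every route is
  rejected is counted as one cell and flagged unsplittable; triangles
  whose arc or chord rasterises empty are discarded with a warning.

## Evaluation

Matching predicted regions to true cells is a stated proxy for a
pathologist's judgement: greedy one-to-one matching by descending
pixel overlap, accepting IoU ≥ 0.5 or predicted-centroid-inside-truth.
A matched pair is a true positive; surplus predictions are false
positives (over-segmentation), unmatched true cells false negatives
(under-segmentation); precision, recall and F-measure are reported as
percentages.  Empty-versus-empty is defined as 100 %.

## What the synthetic scenes emulate — and what they do not

`synthetic.make_scene` generates 512×512 binary scenes: round single
cells (a fraction mildly elliptical, axis ratio ≤ 1.5), chain-shaped
clumps of 2+ partially overlapping discs (centre distance 1.1–1.6
radii by default), single-pixel noise specks and single-pixel interior
holes, with exact per-cell ground truth captured before noise
injection.  Cell radii are hierarchical — one base radius per image
drawn so realised radii span 8–14 px across seeds, with ±10 % per-cell
variation within an image — matching the within-image size homogeneity
of a tumour section that assumption 1 relies on.  All randomness comes
from one seeded generator; the same spec is bit-reproducible.

The scenes do **not** emulate: segmentation errors of a real
colour-image front end (ragged contours, under-/over-segmented
foreground), texture or staining variation, cells truncated by the
image border, dense packings where three or more cells meet at one
point, or strongly elliptical cells.  Passing tests therefore show the
splitting machinery is correct on clean, well-separated, round-cell
geometry; they do not certify performance on real H&E segmentations,
where mask quality dominates.

Problem sizes used by the default test run and the acceptance script —
100 scenes for counting recovery, 100 scenes for stage-1 rates, 50
random configurations per clump family, a 3×3 radius/overlap grid for
splitting-point geometry, 100 random 20×20 seed sets for the distance
engine — were chosen so the complete run finishes in about a minute on
one CPU while keeping binomial noise on the reported rates to a few
percent.

## Known limitations

- **Shallow overlaps are sub-resolution.**  A pinch between discs of
  radius ≲ 9 px at centre distance ≲ 1.25 radii leaves a hull deficit
  of only a few pixels, which rasterisation (and the closing) can
  erase entirely; such clumps are counted as one cell.  This is the
  dominant residual error of the end-to-end run (a few percent
  under-count) and mirrors the method's stated inability to split
  highly overlapped cells with few contour convexities.
- The area rule presumes within-image size homogeneity; mixed
  populations (e.g. a large single cell among small ones) produce
  residual PO objects, which are counted as single and logged.
- Chain clumps are split sequentially by pairwise cuts; a clump of
  k ≫ 3 cells with irregular geometry may be only partially separated.
- The one-pixel cut removes a path's worth of foreground (no
  restoration), so fragment areas are biased low by half a path each;
  counts are unaffected.
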