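# Methods

This note documents the models, conventions and numerical choices behind
`pbbline`, and what the synthetic tests do and do not establish about real
lung-ultrasound (LUS) data.

## Coordinate and box conventions

Pixel coordinates are continuous, origin at the top-left, x to the right,
y downward, 0-based. A polygonal bounding box (PBB) is the 4-tuple of
vertices `(x1,y1),(x2,y2),(x3,y3),(x4,y4)` under the ordering constraints
`y3,y4 ≥ y1,y2` (bottom vertices at or below top vertices), `x1 ≤ x2` and
`x4 ≤ x3`. With y growing downward this matches B-line anatomy: the short
top edge sits on the pleural line, the longer bottom edge at depth.
`canonicalize_vertices` relabels four arbitrary points into this order by a
stable `(y, x)` sort — the two smallest-y points become the top pair, ties
broken deterministically. Constructors do not force the constraints,
because the ordering loss must be able to score violating quads.

## Polygon geometry

Areas use the shoelace formula; IoU uses exact polygon clipping (shapely's
GEOS backend — the standard computational-geometry route for simple
polygons, convex or not). Three policies matter:

- **Degenerate polygons** (collinear vertices, zero area) have IoU 0
  against everything, including themselves — this defines away the 0/0
  union case.
- **Self-intersecting input raises** rather than returning a misleading
  number.
- **Identity returns exactly 1.0** so `1 − IoU(p, p)` is exactly 0 (GEOS
  self-intersection is accurate only to ~1 ulp).

`reduce_to_quad` converts an N-vertex polygon to a canonical quad by
choosing the 4 ring-ordered vertices of maximum quadrilateral area (convex
hull first above 12 vertices). Two design points were settled empirically
during development:

- *Axis-extreme reduction is unsound for slanted wedges*: the topmost and
  leftmost vertices coincide on a leaning B-line, which collapses the quad
  to a zero-area segment. The max-area subset recovers the true corners of
  wedge-like shapes instead.
- *Triangles* (a wedge whose narrow top edge was merged by simplification)
  become quads by duplicating the apex — the vertex opposite the shortest
  edge — which preserves area exactly and keeps the "collapsed top edge"
  semantics of a B-line origin point. If canonical relabeling would ever
  scramble a sliver into a self-touching ring, the ring order is kept
  instead (cyclic chords of a simple ring cannot cross).

## Non-maximum suppression

Greedy, class-aware, scored by polygon IoU: drop detections below the
confidence threshold, visit the rest in descending confidence (ties keep
input order), suppress a detection iff a kept same-class detection overlaps
it with IoU ≥ the threshold **and** IoU > 0. The strict-positivity clause
makes the threshold-0 limit meaningful (one detection per overlapping
cluster; disjoint detections survive). Defaults (IoU 0.45, confidence 0.25)
are the detector family's conventional values, exposed in config.

## Loss family

All losses are pure functions over already-decoded coordinates; gradients,
optimizers and training loops are out of scope (the reference recipe —
AdamW, lr 0.01, momentum 0.937, weight decay 5e-4, 500 epochs, batch 16,
320×320 inputs — is recorded as configuration constants only).

- `L_CIoU = 1 − IoU(p_box, t_box)`: despite the conventional "CIoU" name
  this is the plain overlap complement, with no center-distance or
  aspect-ratio penalty; the formula is authoritative over the name.
- `L_order = (1/6) Σ max(0, p_i − p_j)²` over exactly the six ordering
  constraints (`y3,y4 ≥ y1,y2` expands to four pairs, plus `x1 ≤ x2` and
  `x4 ≤ x3`) — the only pair set consistent with the 1/6 normalizer. A
  single unit violation scores 1/6; satisfied quads score 0.
- `L_vertex`: SmoothL1 with β = 0.11, averaged over the 8 coordinates
  (mean keeps the term on the same unit scale as the IoU term; the
  function is continuous at |d| = β with value β/2).
- `L_obj`: sum of per-cell binary cross-entropies over all anchor-cells,
  probabilities clamped to [1e-7, 1−1e-7]. Targets are hard {0, 1} by
  default (matched anchor-cells = 1), with soft IoU targets as an option.
- `L_dfl`: for a continuous target `t` bracketed by `t_l = ⌊t⌋` and
  `t_r = t_l + 1`, the proximity-weighted cross-entropy
  `(1/N) Σ [CE(p, t_l)·w_l + CE(p, t_r)·w_r]`; an integer target reduces
  exactly to plain cross-entropy at its bin.
- `L_seg`: mask BCE summed over pixels and divided by the bounding-box
  pixel area.
- Totals: `λ_box·L_box + λ_obj·L_obj` (anchor variant) and
  `λ₁·L_obj + λ₂·L_CIoU + λ₃·L_dfl + λ₄·L_seg` (segmentation variant),
  both linear in their weights. Default λ values (box 0.05, others 1.0)
  are config-level defaults, not claims about any trained model.
- **Autobalance**: when dynamic objectness weighting is on, each detection
  scale carries a factor following the EMA
  `f ← 0.9999·f + 0.0001/L_obj(scale)`, initialized at 1 and clamped
  positive. The contract (positive, slowly varying, per scale) is what
  tests pin; the exact decay is a tunable.
- **Anchor matching** is shape-based: a polygon matches an anchor prior
  when `max(w/p_w, p_w/w, h/p_h, p_h/h) < 4` for its minimum bounding
  rectangle; polygons may match several anchors or none.

PBB vertices are *not* decoded from raw head logits: only the axis-aligned
decode (`σ`/`exp` equations above) is defined. The losses consume decoded
coordinates, which keeps the package agnostic to how a head parameterizes
the four vertices.

## Mask → polygon

Probability masks binarize at 0.5. Connected components use
8-connectivity; each component's outer boundary is traced along the 0.5
level set between pixel centers (sub-pixel, orientation normalized to
positive shoelace sign; holes are discarded — B-lines are solid bright
wedges). Components with outline area < 10 px² are dropped as speckle
(config default; no filter value is prescribed by the procedure itself).
Simplification is Ramer–Douglas–Peucker at
`ε = 0.02 × arcLength(contour, closed)`: the closed ring is split at two
mutually far anchor vertices so the result is independent of the ring's
starting point, each open chain is simplified iteratively (no recursion
depth limit), and every original vertex stays within ε of the simplified
boundary. Vertex counts are whatever the shape demands — rectangles
collapse to 4 points, complex outlines keep more; nothing forces quads at
this stage. On 256×256 rasterized rectangles and B-line-like trapezoids
with pixel-aligned corners this recovers corners within 2 px and IoU
≥ 0.95; note that a very narrow top edge (shorter than ε) legitimately
merges into a single apex, which is why the quad reducer handles triangles.

## Preprocessing

- **Otsu threshold**: 256-bin histogram, between-class variance computed
  by cumulative sums, smallest maximizing threshold on ties (`argmax`
  returns the first maximum); pixels strictly above are foreground.
  Constant images raise. Verified against a naive exhaustive search.
- **Morphology**: disk-structured opening (radius 2) then closing
  (radius 5), radius 0 = skip. The radii are exposed; defaults chosen to
  remove speckle islands and bridge speckle holes at the 320-px scale.
- **RoI extraction**: binarize at Otsu, refine, label, take the largest
  component's bounding rectangle. An all-bright frame is its own RoI; an
  all-black frame has none (error). The crop offset is returned so
  detections can be mapped back to frame coordinates.
- **Inpainting**: region pixels are replaced by the exact solution of the
  discrete Laplace equation with the surrounding pixels as Dirichlet data
  (sparse direct solve). This is the cleanest formulation of a
  neighbor-mean diffusion fill: it satisfies the maximum principle exactly
  (filled values bounded by the ring) and leaves out-of-region pixels
  bit-identical. Regions are small text boxes, so the sparse system stays
  tiny.
- **Text detection is pluggable**: a stub detector (caller-supplied boxes)
  and a heuristic detector (small bright components whose bounding boxes
  hug the frame border, merged when close) ship with the package; a real
  OCR engine slots in behind the same `detect(img)` interface. No trained
  text model is bundled. Default order is text removal *before* cropping,
  so border labels influence neither the threshold histogram nor the
  contour; the reverse order is available per config.

## Augmentation

Horizontal flip maps `x → width − 1 − x` (pixel-center convention, an
exact involution) and re-canonicalizes each quad, because mirroring breaks
`x1 ≤ x2`/`x4 ≤ x3`. Mosaic builds a 2-tile-per-side canvas, jitters the
center uniformly over the central 50%, and places each input with its
inner corner at the center, so tiles never overlap; labels follow the
per-tile scale/translation, are clipped to the canvas by
polygon-rectangle intersection, fragments under 1 px² are dropped, and
clipped shapes reduce to quads via the max-area subset (an option keeps
N-vertex clipped polygons). Fully visible polygons are carried exactly, so
areas are preserved at scale 1.0. All randomness flows through an injected
seeded generator; outputs are bit-reproducible.

## Evaluation

Greedy one-to-one matching in descending confidence order: a detection
claims the unmatched same-class ground truth with the highest polygon IoU
and counts as a true positive when that IoU ≥ 0.5 (configurable);
unmatched ground truths are false negatives. Conventions: P = 1 when there
are no predictions, R = 1 when there is no ground truth. AP integrates the
precision-recall curve under the monotone-decreasing precision envelope
with all-point interpolation, pooling confidence-ranked detections across
images (matching stays per image); mAP averages over classes, with a
single class mAP = AP. mAP@0.5 is the default; a 0.5:0.95 sweep is a flag.
IoU is invariant under the per-axis normalization of the label format, so
directory-level evaluation does not need the true image size.

## Synthetic phantom

The generator emulates the phenomenology of a convex-probe B-mode frame,
not its acoustics:

- **Geometry**: 320×320 frame (the detector input size); fan sector from
  an apex 30 px above the frame, radii 50–330 px, half-span 30°; pleural
  arc at 40 px depth below the sector top; A-line arcs repeating at
  pleural-depth multiples; 0–5 B-line wedges, each the exact rasterization
  of its ground-truth quad with corners on the pleural and outer arcs.
  Wedge half-angles are absolute: 0.030–0.050 rad at the pleura,
  0.055–0.085 rad at depth (≈10–20 px top, ≈35–55 px bottom widths), i.e.
  discrete B-lines; confluent mode renders a single wedge spanning about
  half the sector. Wedges that cannot fit the span side by side raise.
- **Intensities** (before speckle): background 5, tissue sector 110,
  A-lines 150, pleura 185, B-lines 235. The ladder was chosen so the
  *frame histogram is bimodal between background and sector* — as in a
  real export, where the exterior is black and the scan area mid-gray —
  which is the property the Otsu-based RoI stage relies on. (An earlier
  iteration with much wider wedges put ~23% of the frame at high
  intensity and broke that bimodality; real B-lines are tens of pixels
  wide, and the defaults were fixed accordingly before the acceptance
  tests were frozen.)
- **Speckle**: multiplicative log-normal, `I · exp(σZ − σ²/2)` with
  σ = 0.15 by default — controllable and mean-preserving, with no claim of
  Rayleigh/Nakagami realism. Text labels are bright dithered glyph blocks
  stamped after speckle (burned-in overlays are crisp).
- **Determinism**: everything derives from one integer seed; dataset
  writing derives per-image seeds by hashing `(master_seed, index)`, so
  regenerated datasets are byte-identical.

What the phantom does *not* model: depth-dependent attenuation and focal
banding, rib shadows, pleural irregularity, motion blur, probe-specific
post-processing, and genuinely confluent textures. Passing the synthetic
loop therefore demonstrates that the stack's stages compose correctly on
wedge-shaped bright artifacts with known truth — it does not certify
clinical performance, which requires annotated LUS data and a trained
segmentation or detection network in place of the thresholding stage.

## Reference detection pipeline

`detect_blines` chains the stages on one frame: preprocess (optional text
removal, RoI crop) → median filter (5×5; the median of the log-normal
speckle restores ≈0.99 of nominal intensity, flattening noise without
shifting step edges) → fixed threshold 210 (between the filtered pleura
≈183 and B-line ≈232 levels) → 3×3 binary closing → `mask_to_pbbs` →
max-area quad reduction with mean-brightness confidence → polygon NMS →
translate by the RoI offset. A trained segmentation network would replace
only the filter-and-threshold step. Benchmark sizes (20 phantoms per
setting) keep the full loop and the acceptance script in the tens of
seconds on one CPU while exercising 40+ ground-truth wedges per run.

## Known limitations

- Canonical relabeling assumes a wedge-like quad; for arbitrary rotated
  quads (e.g. a thin diamond) the `(y, x)`-sort pairing can produce a
  self-intersecting ring, which geometry functions reject rather than
  mis-measure. This matches the artifact domain — B-lines have distinct
  top and bottom edges — but makes the type unsuitable for general
  oriented-box work.
- The heuristic text detector is a fixture-grade stand-in: it finds
  bright glyph blocks near borders and may flag small bright speckle
  regions near the sector rim; inpainting such false positives is visually
  harmless but a real OCR backend is the intended production detector.
- `approx_polygon`'s vertex count is monotone in ε for the contours
  produced here, but RDP gives no universal monotonicity guarantee on
  adversarial polylines.
- The DFL container holds one probability vector per target; batched
  tensor layouts used by real heads must be adapted at the call site.
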