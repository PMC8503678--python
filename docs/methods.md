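# Methods

## Screening model

The pipeline classifies *clusters*, not pixels.  Stage one proposes
candidate clusters from color alone: stained chromatin is far more
saturated than the pale smear background, so the HSV saturation channel
`S = (max − min)/max` (with `S = 0` at black) is thresholded and the
surviving pixels are closed with a disk and labelled with 8-connectivity.
Two geometric filters then encode what a cytologist would call "a cohesive
clump of large cells": surface area strictly greater than 60 000 px, and a
fill ratio of at least 30 % of the minimum-area rotated bounding rectangle.
The strict/inclusive split follows the method's wording ("bigger than",
"at least"); the area test is applied first, so a candidate failing both
is reported as an area rejection.

Stage two partitions each accepted cluster into fixed-size square sections,
scores each section with a pluggable model, and calls the cluster cancerous
iff the plain arithmetic mean of the section scores strictly exceeds the
classification threshold τ.  Two operating points matter: τ = 0.426
(high specificity) and τ = 0.046 (high sensitivity).  The source tables
print the low threshold variously as 0.046, 0.045 and 0.0459; the package
treats τ as a free parameter and does not resolve that discrepancy.
Because the mean is fixed per cluster, the set of cancer calls is
monotone in τ by construction.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_area_px` | 60 000 | area filter on candidate aggregates (strict >) |
| `min_fill_ratio` | 0.30 | fill of the minimum rotated rectangle (≥) |
| `binarization` | Otsu | saturation threshold; the method names none, so the parameter-free Otsu (256-bin histogram) is the default, with a fixed-threshold override |
| `closing_radius_px` | 5 | merges touching cells into one aggregate; the method is silent, 5 px spans inter-cell gaps at generator scale |
| `tile_size_px` | 128 | section size; unstated in the method, chosen to hold a few cells at generator scale |
| `min_inside_fraction` | 0.5 | a section is scored only if half its pixels lie on the cluster mask; prevents background-dominated sections (the best-covered section is kept if none qualifies, so every cluster gets ≥ 1) |
| τ | 0.426 | classification threshold on the mean section score |

"Minimum bonding rectangle" is read as the minimum-area *rotated*
rectangle — the literal minimum, computed over pixel-corner points so a
1-px line has positive width and `w·h ≥ area` always holds; an axis-aligned
variant is available behind `rect_mode`.  Pixels are the native unit
throughout; no physical calibration (40× vs 100×) is modelled, so the
60 000 px filter is resolution-agnostic.

## Reference scorer

The published realization of the section scorer is a 27-layer CNN whose
weights are not available; the package deliberately treats the scorer as an
interface, because the reproducible method is the aggregation rule, not the
weights.  The bundled reference scorer is a logistic regression over seven
hand-crafted proxies of the stated malignant morphology: mean saturation,
mean darkness (1 − V), dark-blob count and mean area (candidate
hyperchromatic nuclei at darkness > 0.45, 8-connected), the fraction of
dark pixels in blobs ≥ 200 px (large-cell proxy), bright holes enclosed by
dark blobs (vacuole proxy), and local intensity SD (texture).  Features are
standardized by training-set mean/SD stored in the model; training is
deterministic under a seed and reports held-out accuracy from an internal
25 % split.  Models serialize to JSON and round-trip exactly.

## Statistics

* Cohen's κ uses p_o, p_e from the 2×2 margins; its SE is the
  large-sample delta-method form (Fleiss, Cohen & Everitt 1969), matching
  common statistical-package output, with a Wald 95 % CI.  The six
  qualitative bands follow the convention <0, 0–0.20, 0.21–0.40,
  0.41–0.60, 0.61–0.80, 0.81–1.0; band edges belong to the lower band.
* ICC is the one-way random-effects model.  The published F/ICC pair
  satisfies ICC = 1 − 1/F, which identifies average measures ICC(1,k);
  both ICC(1,1) and ICC(1,k) are reported.
* ROC curves are empirical over unique score thresholds; AUC is
  trapezoidal and therefore equals the Mann–Whitney statistic with the
  ½-credit tie convention.  Single-curve SE is Hanley–McNeil; the paired
  comparison of two scorers on the same items is DeLong's
  covariance-based Z-test (two scorers with identical scores give z = 0,
  p = 1; a degenerate non-zero difference is flagged undefined rather
  than forced).
* The Youden point maximizes tpr − fpr over the curve's own thresholds,
  breaking ties toward the higher cutoff.
* `split_dataset` assigns ⌊0.8·n⌋ items to training via a seeded uniform
  permutation (20 748 → 16 598/4 150).
* Degenerate inputs (zero denominators, pe = 1, zero-variance tables) are
  flagged as undefined (`None`), never silently coerced to 0.

## Table reconstruction

A printed rate `v` at `dp` decimals is interpreted as the half-open
interval `[v − 0.5·10⁻ᵈᵖ, v + 0.5·10⁻ᵈᵖ)` (round-half-up, the display
convention of the usual spreadsheet/statistics tools; the audit tolerances
absorb the half-even alternative).  For every prevalence `P ∈ [1, N−1]`
the integers TP and TN compatible with the printed sensitivity and
specificity are derived by exact integer inequalities, and kept when the
implied accuracy also rounds to the printed value.  The *central* solution
solves `acc = sens·p + spec·(1 − p)` for real `p` and rounds
`P = round(N·p)`, `TP = round(sens·P)`, `TN = round(spec·(N−P))`.
Audit tolerances — |Δκ| ≤ 0.01, |ΔPPV/NPV| ≤ 0.005 — were chosen as the
propagation of 3-dp input rounding and are confirmed empirically by the
widths of the feasible ranges.  An empty feasible set is reported as an
inconsistent row, not an exception; a row whose every prevalence is
feasible (e.g. sens = spec = acc = 1) is flagged as having indeterminate
prevalence, and a positive count can be pinned explicitly.  Per-item
rating vectors are *not* reconstructable from marginals, so the published
multi-rater ICC of 0.827 and the test-set AUCs are not reproduced from
tables — only the identity ICC = 1 − 1/F and the per-row kappas are.

## Synthetic scenes

The generator emulates the features the detector and scorer key on:
a pale noisy background; small pale hematopoietic cells; cancer clusters
grown by accreting overlapping ellipse cells around a centre until the
union footprint reaches a target area (default 80 000–120 000 px, safely
above the area filter), each cell rendered as a thin basophilic cytoplasm
rim, a large dark-blue nucleus (92 % of the cell radius, so the
high-saturation footprint stays close to the truth mask) and occasional
bright vacuoles; red-cell clumps of low-saturation pink cells at 8 000–
25 000 px (below the area filter); and dark streaks/specks as staining
artifacts (small or thin, so the geometric filters reject them).
`cluster_cohesion ∈ [0, 1]` sets how deeply a new cell overlaps its
anchor (0 = tangent).  Soft, anti-aliased edges come from a final 0.7 px
Gaussian blur of the float canvas.  All randomness flows from a single
`default_rng(seed)`, so identical specs give byte-identical images;
ground-truth areas are exact pixel counts of per-cluster masks stored in
an 8-bit label raster (≤ 255 objects per scene); objects are placed
disjointly, with a named `PlacementError` when a requested object cannot
fit.

What the generator does **not** emulate: true Wright-Giemsa chromatics and
stain variability, multi-layer (z-stack) focal planes, cell-density
gradients toward the feather edge, nucleoli/mitoses, and touching objects
of different classes.  Passing tests therefore demonstrate the
correctness of the pipeline's logic and its discrimination on scenes that
honor the stated morphology — not clinical-grade performance on real
smears, which the published study measured on proprietary slides with a
trained CNN.

## Problem sizes in the test suite

The oracle-equivalence suites run component labelling against flood fill
on 200 random 64×64 masks, AUC against exhaustive pair counting on 100
instances, the rectangle and Youden scans on dozens of random cases, and
the feasible-set enumeration against a full scan for n ≤ 200.  The
end-to-end discrimination check trains the reference scorer on 200
balanced tiles and evaluates 200 held-out truth clusters per seed for
three seeds; at these sizes the whole suite completes in minutes on one
CPU while the separation margin (AUC ≈ 1 vs the 0.95 bound) leaves the
result insensitive to the exact counts.

## Known limitations

* The scorer interface ships only the logistic reference model; no
  convolutional scorer is bundled, so published CNN-specific numbers
  (sensitivity 56.6 %, specificity 91.3 %, AUC 0.865 on the proprietary
  test set) are out of reach by design.
* The Youden index printed by the study (0.808 at cutoff 0.485) is not
  consistent with its own printed sensitivity/specificity at nearby
  thresholds (sens + spec − 1 ≈ 0.48); the implementation follows the
  definition and makes no attempt to match 0.808.
* The two consensus-subset rows of the published table (n = 1147 and
  n = 4295, which do not sum to 5469) are audited as standalone rows only.
* Otsu's threshold on a nearly empty scene can sit inside background
  noise; blank-scene detection still returns zero candidates because the
  area filter removes the speckle, but pathological all-noise inputs are
  best run with a fixed threshold.
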