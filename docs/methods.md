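# Methods

`silageqc` implements the quality-control computations used when building
instance-annotation datasets of whole-plant corn silage (WPCS): descriptive
statistics over harvest machine settings, inter-annotator agreement, physical
quality scores derived from polygon geometry, COCO-standard detection
evaluation, and the teacher–student semi-supervised update rules.  No public
image dataset of annotated WPCS exists, so the package ships a synthetic-data
generator that reproduces the statistical structure those analyses assume and
every stage is exercised on simulated data.

## Geometry and calibration

Instances are simple polygons in pixel coordinates (origin top-left,
0-based), stored as open counter-clockwise rings.  Self-intersecting input
is rejected, not repaired: silent geometry fixing would change areas and
axes unpredictably.  A single calibration constant `px_per_mm` (default 20,
the capture rig's resolution) converts to physical units.

Two published statistics columns — "Avg. Major/Minor Axis Length" — never
come with an axis definition.  We define the axes as the side lengths of the
minimum-area enclosing rotated rectangle, because both physical rules read
an axis as a caliper extent: the sieve passes a particle whose smallest
cross-section fits, and the overlength indicator is exceeded "along any
axis" by the longest extent.  A `moment_ellipse` mode (axes of the
area-equivalent second-moment ellipse) is available for sensitivity checks;
on elongated particles it reads roughly 15 % longer than the rectangle side.
Polygon area is the shoelace formula; IoU is exact polygon
intersection-over-union (via constructive geometry, with operand order fixed
so `iou(a, b) == iou(b, a)` bitwise).

## Quality rules

* **Minimum size.**  Annotators were shown a 1 mm-radius indicator and told
  to annotate only fragments extending beyond its 2 mm diameter.
  `min_size_filter` therefore keeps instances with major axis ≥ 2 mm
  (boundary inclusive — a fragment exactly the indicator's size was to be
  annotated).
* **CSPS.**  The Corn Silage Processing Score is the percentage of kernel
  material passing a 4.75 mm sieve.  From images we use the minor axis as
  the sieve measure (strict `<` the aperture: a particle exactly the
  aperture's size does not pass) and weight by projected polygon area, the
  image proxy for the mass fraction the laboratory score uses.  Count
  weighting and alternative measures (major axis, area-equivalent diameter)
  are provided because the linear measure used in earlier sieving work is
  not restated.  An empty fragment set yields an absent estimate, never 0.
* **Overlength.**  A stover particle is overlength when its major axis
  strictly exceeds 1.5 × TLOC (at a 4 mm cut, the threshold is 6 mm).  The
  accepted/non-accepted leaf distinction depends on leaf structure that a
  polygon alone cannot supply, so it is an input label, never computed.

## Dataset statistics

`summarize` produces one row per machine-setting group plus a Total row.
Instances-per-image is defined as total instances / total images, rounded
half-even to two decimals.  Several printed per-row cells in the published
season table do not equal that ratio (and one season's total row exceeds the
sum of its printed rows); the module computes the ratio and documents the
discrepancy rather than emulating unexplained cells.  `trend_report` checks,
per TLOC stratum, that median fragment size is non-decreasing and
instances-per-image non-increasing along the Processor Gap, with Spearman
rank statistics; violations are flagged, since real pre-sanity-check
harvests often violate the trend.

## Agreement

Two annotators agree on an instance when their polygons have IoU > 0.5.
Matching is one-to-one and greedy by descending IoU with deterministic tie
breaks (an optimal-assignment mode exists for verification; on random
non-adversarial scenes the two coincide, and greedy can only ever find
fewer pairs).

Cohen's kappa needs paired categorical ratings, and no construction is
given for turning two instance *sets* into ratings.  We rate
"annotated / not annotated" over units defined as the classes of the
cross-annotator match graph (matched pair → both annotated; unmatched
instance → one side only) plus per-image background pseudo-units rated
not-annotated by both, with a per-image budget defaulting to the maximum
per-image unit count.  This yields κ = 1 for identical sets, κ ≤ 0 for
disjoint non-empty sets, and a proper 2×2 chance correction.  Published
agreement tables print 0 for pairs that plausibly had negative
chance-corrected agreement, so the headline value clips negatives at zero;
the raw value is always retained.  The degenerate case P_e = 1 (both raters
constant) is defined as 1 for all-agreement and 0 otherwise, and flagged.
Asymmetric overlap counts that cannot arise under one-to-one matching are
not emulated.

## Detection evaluation

`evaluate_detections` reimplements the COCO protocol: per class, detections
in descending score order are matched greedily to the unmatched
ground-truth instance of highest IoU at each threshold in 0.50:0.05:0.95;
AP is monotone-envelope precision sampled at 101 recall points (the grid is
built from exact decimals — accumulating 0.01 steps drifts by an ulp, which
matters because sampled recalls are small-denominator rationals); AR@k caps
detections per image at k.  Metrics are ×100; overall values average the
classes with ground truth; there is no area-range breakdown and no crowd
handling.  Polygon IoU is the default (annotations are polygons), box IoU is
available for bounding-box detectors.  The implementation is verified
against an exhaustive brute-force oracle (naive matching loops, exact PR
integration) to 1e-9 on random small scenes.

Pearson correlation of image-derived CSPS against sieved records pairs
samples by id, reports r per calendar week and pooled, raises on unpaired
ids, and reports an absent value on zero variance.  `compare_runs` gives
per-metric deltas in percentage points and ratios over a baseline row, with
NaN propagation for diverged runs.

## Synthetic data

The generator emulates what the analyses need and nothing more:

* **Counts.**  Kernel fragments per image are negative-binomial with mean
  `base_rate · exp(pg_slope · pg_mm)`; overdispersion matches the
  within-setting spread visible across real sequences.  Defaults
  (`base_rate` 38.8, `pg_slope` −0.327, dispersion 8) reproduce the
  qualitative sanity-checked-season pattern of ≈28 instances/image at PG
  1 mm falling to ≈10 at PG 4 mm, without claiming exact values.
* **Sizes.**  Major axes are lognormal with location increasing in PG
  (median ≈3 mm at PG 1 to ≈5 mm at PG 4, log-sd 0.35); particles are
  convex hulls of noisy ellipse discretizations (12–24 vertices), giving
  valid simple polygons with controllable axes.
* **Stover.**  Overlength particles appear at a Poisson rate decreasing in
  TLOC, sized just above the 1.5 × TLOC threshold, with a fixed class mix
  over the four stover classes.
* **Annotators.**  A profile drops instances with probability
  `miss_base + miss_size_slope · major_mm` (smaller particles missed more),
  jitters vertices, adds Poisson spurious instances, and with `merge_prob`
  replaces closely grouped same-class pairs by their convex-hull union —
  the grouped-fragment ambiguity real annotators face.  No quantitative
  noise magnitudes exist for the real annotators; profiles are free
  parameters, not estimates.
* **Detectors.**  True positives are jittered ground-truth outlines kept
  with a size-dependent recall probability and Beta-distributed scores;
  false positives are random blobs with their own score distribution.
* **Sieving.**  The physical CSPS of a sample is the area-weighted passing
  fraction of its fragments plus Gaussian measurement noise, clipped to
  [0, 100].  Its pass/fail logic is written independently of the estimator
  so their noise-free equality is a real cross-check.

Every generator is a pure function of (inputs, seed); randomness is split
into counter-based per-image substreams, so per-image output is independent
of image order.  What the simulation does **not** model: image pixels,
occlusion geometry beyond the merge rule, annotator-specific systematic
styles, within-field spatial correlation.  Passing tests therefore show the
*computations* are correct under the assumed statistical structure, not that
the structure matches any particular real harvest.

## Teacher–student rules and the toy loop

The update rules are pure functions: confidence gating
(`score ≥ threshold`, scores stripped so survivors act as ground truth),
EMA refinement `alpha·teacher + (1−alpha)·student` (default 0.9996), and
the combined loss `sup + weight · unsup`.  Full-scale defaults are 50,000
iterations with a 10,000-iteration burn-in.

`run_toy_ssl` executes the loop literally on a deliberately tiny problem:
a logistic scorer separating two 1-D Gaussian clusters (±1, sd 0.35), 8
labelled points, 12-item scenes, weak/strong augmentation as small/large
input noise (sd 0.05 / 0.4).  Items the teacher scores above the threshold
become positive pseudo-labels; everything else becomes background, exactly
as sub-threshold detections do in detection pseudo-labelling.  A low
threshold therefore injects false-positive labels, a high one false
negatives, and a mid threshold is best — the trade-off the published
hyper-parameter sweep probes.  The toy claims only the mechanism, never any
absolute detection metric.

Scaling choices: the toy runs 240 iterations with a 60-iteration burn-in,
and the EMA decay scales with the run length (0.95, preserving the ratio of
the teacher's averaging timescale to the post-burn-in run: 1/(1−α) = 2500
of 40,000 iterations at full scale, 20 of 180 in the toy).  The supervised
loss is full-batch, so a weight-0 run is RNG-identical to the independent
supervised-only trainer — the degenerate configuration (weight 0,
threshold 1) matches that baseline exactly, parameter for parameter.
A run whose loss exceeds a ceiling is reported as diverged rather than
raised, since sweep tables print such runs as missing rows.

## Numerical conventions

* Ratios rounded half-even to 2 decimals in statistics tables.
* Sieve pass strict `<`, overlength strict `>`, minimum-size keep `≥`.
* Greedy tie-breaks: by descending IoU then lexicographic instance ids
  (matching); by descending score then id (evaluation) — making all results
  invariant to input ordering.
* Degenerate polygons (< 3 distinct vertices, zero area, self-intersection)
  are rejected at construction with the offending ids named.

## Problem sizes

The test suite and analysis scripts run at desk scale: 40–240 simulated
images per experiment, 200 images per Processor-Gap level for the trend
sweep, 100 random scenes for the evaluator/matching oracles, and 50 seeds
for the teacher–student Monte Carlo.  These sizes give Monte-Carlo standard
errors comfortably inside the margins the tests assert.
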