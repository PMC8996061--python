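# Methods

## Sampling model

A labelled cloud of `n` points with class counts `n_c` (C = 8 organ
classes) is chunked by drawing `a` anchor points and cutting, for each
anchor, the `min(k, n)` nearest neighbours by Euclidean distance on the
x/y/z coordinates only — colour is a per-point feature, not geometry.  The
neighbour search runs over the entire cloud, so a chunk anchored on a
minority organ still contains its true spatial context.  Exact distance
ties are broken by ascending point index, which makes chunk membership
platform-deterministic; the anchor (distance 0) is always the first member.

Anchor budgets per class are real-valued under both strategies
(proportional and inverse-proportional to the class fractions) and are
integerised by largest-remainder (Hamilton) rounding, remainder ties broken
in class-scheme order.  This guarantees `Σ a_c = a` exactly and makes the
two strategies coincide on a uniform distribution.  Classes absent from a
cloud are excluded from the inverse-allocation normaliser and receive zero
anchors, since an anchor cannot be drawn from an empty class; the inverse
strategy therefore requires at least two present classes.  Within a class,
anchors are drawn uniformly without replacement; if a class is asked for
more anchors than it has points the draw falls back to with-replacement and
logs a warning, so small clouds degrade gracefully instead of failing.

Randomness is organised as one root seed with per-cloud substreams derived
from `(seed, cloud_index)`, so adding a cloud to a training set never
perturbs the chunks drawn for the others.

## Imbalance and composition diagnostics

Class imbalance is measured as Shannon entropy of the class fractions in
bits, with the standard convention `0·log2 0 = 0`.  Entropy is kept at full
precision internally and rounded to one decimal only in reports.  Training
set composition pools chunk-member labels counting a point once per chunk
that contains it: overlapping chunks deliberately double-count, because that
is the composition the segmenter actually trains on.  Chunk composition
(distinct classes per chunk) is summarised box-plot style: quartiles,
whiskers at the extreme observations within 1.5×IQR of the quartiles, the
rest as outliers.

## Coverage chunking and vote merging

Unlabelled test clouds are chunked by iteratively drawing one anchor
uniformly from the not-yet-covered points and cutting its k-neighbourhood
over all points, until the uncovered set is empty; termination within n
iterations is guaranteed because each chunk covers at least its anchor.  A
`batch_size` option draws several anchors per iteration for speed on large
clouds but defaults to 1 for fidelity to the one-at-a-time procedure.
Merging accumulates one vote per (chunk, point) pair — a chunk cannot vote
twice for the same point since members are unique — and picks the modal
label, resolving ties uniformly at random from the seeded stream, so
tie-free merges are seed-independent.

## Evaluation

Confusion matrices are point-wise over merged full clouds.  Per-class IoU,
precision and recall with zero denominators are reported as NaN and
excluded from the macro mean rather than scored as 0 (and logged): an organ
absent from both truth and prediction carries no evidence.  Report rounding
follows segmentation-literature convention: two decimals for metrics, one
decimal for row percentages.  Paired comparisons use the two-sided Wilcoxon
signed-rank test — exact null for up to 25 non-zero differences, normal
approximation with continuity correction beyond — starred at 0.05/0.01/
0.001; the default pairing unit is one score per (test cloud × class ×
repetition), configurable by the caller since other pairings are defensible.
All-zero difference vectors short-circuit to p = 1.

## Synthetic plants

The generator stands in for scanner data that is not publicly available.
Each cloud is one stylised cucumber plant: a wobbling vertical stem polyline
(cylinder radius 5 mm) with evenly spaced nodes, one petiole (2.5 mm
cylinder, ~85 mm) per node leading to a planar elliptical leaf blade
(~95×70 mm), helical tendrils at alternating nodes, ellipsoidal ovaries at
the lowest three nodes, an apical growing-point cluster, and non-plant
structure split over a pot disc, a gutter plane and a vertical support
wire.  Coordinates are millimetres with z the growth axis; plant height is
drawn in 760–1,950 mm and leaf count in 8–12 per plant unless fixed,
matching mature greenhouse plants.  Per-class point counts are the
largest-remainder integerisation of the target fractions (default: leaf
.789, non-plant .150, stem .027, petiole .015, and .00475 for each of
growing point, node, ovary, tendril — entropy 1.06 bits), so achieved
fractions are exact to <1/n and every class is present.  Organ colours are
class-typical RGB means in an overlapping green gamut plus Gaussian noise
(sd 12, clipped to 0–255); positions get 0.8 mm Gaussian jitter, roughly a
laser-triangulation noise floor.

What the generator reproduces: controllable imbalance, locally
distinguishable organ geometry/colour, and the adjacency that drives real
confusions (nodes and ovaries hug the stem).  What it does not: occlusion
and missing surfaces, botanical leaf shape, within-organ colour gradients,
multi-scan registration artefacts.  Passing tests therefore demonstrate the
sampling mechanism, not field-ready segmentation accuracy.

## Baseline segmenter

The bundled baseline is a Gaussian prototype classifier over 7 per-point
features: height above the cloud minimum, RGB, and the
linearity/planarity/sphericity eigen-descriptors of the local covariance
over each point's 16 nearest members within the chunk.  Features are
standardised with training statistics; a point is assigned
`argmax_c [−½‖x−μ_c‖² + w·log π_c]` with class centroids `μ_c`, empirical
training priors `π_c` and `prior_weight` w = 1 by default.  The prior term
mirrors the frequency sensitivity of a network trained with unweighted
cross-entropy; with w = 0 the rule reduces to plain nearest centroid.  In
practice the sampling-strategy effect shows under either setting — it is
carried mainly by how well minority-class centroids are estimated from the
training chunks — but the prior makes the emulation of loss-based training
explicit.  Classes unseen in training cannot be predicted.  The baseline is
intentionally weak and fast: it exists to make sampling effects measurable,
not to compete with deep segmenters, and positions are re-centred on the
chunk anchor so it sees translation-invariant input.

## Experiments

Experiment 1 compares the two anchor strategies at fixed k; experiment 2
sweeps k over {512, 1,024, 2,048, 4,096, 8,192, 16,384} under the
class-dependent strategy, additionally reporting training-set entropy and
mean classes-per-chunk per k.  Training repeats (default 5) with distinct
derived seeds; summaries report means with Student-t 95% confidence
intervals (the CI method is a documented choice) and Wilcoxon stars.  Test
clouds are always covered with the label-blind procedure regardless of the
training strategy.  The anchor budget `a` is held constant across k by
default; a switch to hold `a·k` constant instead is available.  Each run
writes a manifest (config, seeds, package version) sufficient to reproduce
it bit-exactly.

Default problem sizes in the test suite and examples — 50,000-point plants,
a = 50, k = 512, 10 seeds for the directional strategy comparison; the
k-grid truncated at 4,096 for trend checks — were chosen as the smallest
sizes at which all eight classes are populated well enough for per-class
recall to be defined on every seed.

## Numerical and degenerate-input choices

* `k > n` truncates to n (no padding); `k < 1` is an error.
* Entropy of an empty (all-sentinel) label set is an error, not 0.
* Largest-remainder totals outside `[Σ floor, Σ ceil]` raise.
* Tie-breaks everywhere are deterministic (index order) except vote ties,
  which are defined to be random and seeded.
* The unlabelled sentinel (−1) is excluded from every distribution, never
  evaluated, and rejected by the evaluator.

## Known limitations

* The baseline segmenter's absolute accuracy is far below deep models;
  conclusions transfer only about the *relative* effect of sampling.
* The synthetic generator's organ separability is optimistic (no occlusion,
  clean geometry), so absolute IoU values on synthetic data overstate what
  real scans yield.
* Binary PLY, LAS/LAZ and streaming I/O are unsupported by design.
* Coverage chunking with `batch_size > 1` can produce slightly more chunks
  than the strict one-at-a-time procedure.
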