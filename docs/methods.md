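# Methods

`cephalo` localizes the 26 standard landmarks of a lateral cephalogram
with a cascade of gradient-boosted regression-tree ensembles, augments
training data with landmark-consistent transforms, and evaluates both
raw landmark accuracy and the seven derived angular features that carry
the diagnostic content. This note documents the models, the synthetic
data the package is validated on, the numerical choices, and the known
limitations.

## Landmark schema and angular features

The landmark roster (S, P, Go, N, O, A, B, Me, G, Sn, Ls, Li, PgS, Ur,
Uc, Lc, Lr, ANS, PNS, U6M, U6D, L6M, L6D, SEM, Pn, Co) is fixed; every
array, file and report uses this order. Coordinates are 0-based pixels,
origin top-left, x rightward, y downward. The seven angular features
are:

| feature | definition |
|---|---|
| SNA | vertex angle at N between rays N→S and N→A |
| SNB | vertex angle at N between rays N→S and N→B |
| ANB | SNA − SNB, signed (may be negative) |
| Uc-Ur / S-N | angle between the upper-incisor axis (root→crown, Ur→Uc) and the anterior cranial base S→N |
| Lc-Lr / Go-Me | angle between the lower-incisor axis Lr→Lc and the mandibular plane Go→Me |
| S-N / Go-Me | cranial base vs mandibular plane |
| G-Sn-Pg′ | soft-tissue convexity: vertex angle at Sn between rays to G and PgS |

Vertex angles are unsigned in [0, 180]. Line–line angles depend on the
chosen segment directions (reversing one maps θ to 180 − θ); the
root→crown and S→N / Go→Me conventions above are fixed so values are
reproducible. Whether the "inner" or "outer" incisor inclination is
intended is a convention choice; only error *differences* matter for
evaluation, and those are direction-independent. ANB is reported
signed as the difference SNA − SNB, which makes the identity
`anb == sna - snb` exact by construction.

Per-landmark prediction error is the Euclidean distance in pixels
between predicted and true position; its direction is the angle of
(pred − truth), 0° = image right, 90° = image down, in [0, 360). A
zero-magnitude error has no direction and is reported as NaN and
excluded from circular summaries (atan2(0,0) is undefined).
Directionality is summarized per landmark by the circular mean and the
mean resultant length R̄ ∈ [0, 1] (scipy's directional statistics).

A note on error cancellation in ANB: perturbations that rotate A and B
about N by a common angle change SNA and SNB equally and cancel exactly
in ANB. This is the precise form of the "antagonistic errors"
phenomenon; sliding A and B jointly along the A–B line does *not*
cancel exactly (the subtended angle at N changes), it is only bounded
by |ANB err| ≤ |SNA err| + |SNB err|. The test-suite asserts both
constructions.

## Synthetic cephalogram generator

No public cephalogram corpus ships with this package, so validation
runs on a synthetic generator that emulates the statistical structure
the regression method conditions on — not radiographic appearance. One
subject is produced by:

1. a fixed 26-point template (implementation constants on a 256-px
   canvas, chosen so all seven features are finite, non-degenerate and
   clinically plausible: ANB ≈ +5.4°, G-Sn-Pg′ ≈ 165°, S-N/Go-Me ≈ 25°),
2. a global similarity placement: translation ~ N(0, 25 px) per axis,
   scale ~ N(1, 0.07), rotation ~ N(0, 6°) about the image center,
3. correlated per-landmark deformation: i.i.d. N(0, 4 px) offsets
   smoothed over the landmark 4-nearest-neighbour graph (two rounds of
   a row-stochastic averaging operator), so neighbouring landmarks move
   coherently, a cheap stand-in for biological shape covariance,
4. rendering: smooth splines through anatomically grouped subsets
   (cranial outline, mandibular border, maxilla, incisor axes,
   soft-tissue profile) and small disk marks (porion, orbitale, molar
   cusps) over a linear background intensity gradient, then Gaussian
   blur (σ = 1 px) and additive Gaussian noise (s.d. 5), clipped to
   8 bits.

Placements that push any landmark within 8 px of the border are
resampled (at most 100 times, then an explicit error). Everything is
bit-deterministic given the config seed.

The variation scales were calibrated once against two qualitative
properties the analysis needs the data to have: (a) fixed-magnitude
affine transforms of the reference protocol (±50 px shifts, 10% zoom,
10° rotation/shear) should sit at the edge of, not far outside, the
natural inter-subject variation, so that transformed images behave like
plausible unseen images; and (b) the learning task should remain
sample-limited in the 50–250 image range rather than saturating, so
that data-augmentation experiments have headroom. With a 256-px frame
and the template spanning ~140 px, natural translation beyond ~±40 px
is geometrically impossible (landmarks would leave the margin), which
caps how far property (a) can be pushed — see Limitations.

What passing tests on this generator do **not** show: robustness to
radiographic appearance (soft-tissue gradients, exposure variation,
occlusal artifacts), to annotation noise (synthetic labels are exact),
or to anatomy outside the template's deformation model.

## Cascaded ensemble of regression trees

The predictor follows the classic cascaded-regression design used for
face alignment. A `ShapeModel` holds a mean shape (unit-square
coordinates) and T cascade stages; each stage holds a pool of
shape-indexed feature points and K depth-F regression trees fitted by
gradient boosting with a sum-of-squares loss and shrinkage ν.

- **Initialization frame.** No detector box exists for cephalograms;
  the mean shape is placed by scaling its unit coordinates to the full
  image rectangle.
- **Shape-indexed features.** Each stage samples
  `feature_pool_size` points uniformly over the mean-shape bounding box
  (+5%); each point is stored as (nearest landmark, offset). At
  run time the offset is carried through the linear part of the
  least-squares similarity (closed-form Umeyama fit, no reflection)
  aligning the placed mean shape to the current estimate and attached
  to the anchor's current position. Intensities are nearest-pixel
  lookups; out-of-bounds positions read 0.
- **Trees.** Complete binary trees of depth F. Every node tests
  intensity(a) − intensity(b) > τ for a pool pair (a, b). Candidate
  splits per node: `candidate_splits_per_node` proposals, pairs drawn
  with an exponential locality prior exp(−d/λ) (λ defaults to 0.1 ×
  image width), thresholds uniform over the empirical range of that
  pair's differences at the node; the proposal minimizing the summed
  squared residuals wins, first-sampled wins ties (deterministic under
  seed). Leaves store the mean residual of the examples reaching them;
  an empty leaf stores zero.
- **Boosting.** Each tree's output is added with weight ν and the
  current shapes/residuals are updated after every tree. Because a
  leaf's mean cannot increase the summed squared residual of its own
  members for ν ∈ (0, 2), the mean squared training residual is
  non-increasing across trees and stages; `train_history` records it
  per stage and the suite asserts monotonicity.
- **Oversampling.** Each training image contributes R examples: the
  first starts from the placed mean shape, the rest from ground-truth
  shapes of other randomly chosen training images, giving varied but
  realistic initializations.
- **Defaults.** ν = 0.2, T = 10, F = 1, R = 20 (the tuning optimum on
  the reference task); K = 500, pool 400, 20 proposals per node follow
  common practice for this algorithm family. Tests and sweeps use
  reduced values (K ≤ 50).

Training work scales as F·R·T (×K); the model exposes structural
counters (`n_trees == T·K`, `leaves_per_tree == 2^F`, examples =
n·R) so the proportionality is checkable without wall-clock
benchmarks.

Models serialize to versioned JSON (`format_version: 1`) with full
float precision; the loader rejects unknown versions and malformed or
truncated files, and round-trips predictions bit-identically.

## Landmark-consistent augmentation

Affine kinds — zoom (uniform scale 1 + f about the center), h_shift
(height-axis translation), w_shift (width-axis), shear (x displaced by
tan(θ)·y about the center), rotate (about the center) — warp the image
bilinearly (constant-0 fill, size preserved) and map the landmark
coordinates through the same matrix exactly. The elastic transform
composes a random affine (three reference points displaced uniformly
within ±alpha_affine) with a Gaussian-smoothed random displacement
field (per-pixel uniform[−1, 1], smoothed with σ, scaled by α);
landmarks move by the negated backward field evaluated at their
position — a first-order approximation to the exact inverse, accurate
to O(field gradient), small at σ = 5. Landmarks pushed out of frame
are flagged on the output, never clipped; evaluation excludes flagged
landmarks and any feature depending on one, and the gain experiment
redraws flagged augmented copies. Reference magnitudes: zoom 10%,
shifts 50 px, shear 10°, rotation 10°, elastic α = 100, σ = 5,
alpha_affine = 50; random-policy ranges: ±20%, ±70 px, ±15°.

## Experiments

- **Parameter sweep** (`run_sweep`): one-dimensional slices around a
  base configuration (matching per-parameter tuning panels; a full
  factorial grid would add nothing at desk scale), recording train and
  test error plus the work counters.
- **Transform novelty** (`run_novelty`): one model trained on
  untransformed images, evaluated on untransformed and per-transform
  versions of both splits (2 × (1 + #specs) conditions).
- **Augmentation gain** (`run_gain_curve`): from a 50-image base set,
  grow the training set either with unseen originals or with random
  transforms of the base set; 3 replicate seeds by default (single
  runs are too noisy to compare arms). "Recovery" is reported two
  ways, because "a gain of at least 50%" is ambiguous:
  `ratio_of_gains` = 100·(baseline − augmented)/(baseline − original)
  at matched size (the primary reading), and `error_reduction_pct` =
  the augmented arm's own reduction relative to baseline.
- **Directionality** (`summarize_directionality`): circular mean and
  resultant length per landmark, zero-magnitude errors excluded.

Problem sizes used by the shipped end-to-end checks — 200 generated
images (150/50 split) for the ANB-accuracy check, 50 + 100 + 50 for the
gain check, 105/45 for the novelty check — are desk-scale choices that
keep a full run in minutes on one CPU while leaving every qualitative
effect measurable.

## Known limitations

- **Frame-scale mismatch of fixed-pixel transforms.** The reference
  transform magnitudes are absolute pixels (50-px shifts) while the
  generator's default frame is 256 px with anatomy spanning ~140 px.
  On full-resolution radiographs a 50-px shift is a small fraction of
  the frame; here it is ~20% and geometrically *cannot* lie well
  inside natural placement variation (margins cap translation at
  ~±40 px). Consequently shift-transformed images are genuinely
  out-of-distribution, shift-condition errors dominate the affine
  maximum, and the elastic condition exceeds the affine maximum by a
  factor of ~1.4 rather than an order of magnitude. The qualitative
  ordering — elastic is the single most novel transform — does
  reproduce; the magnitude of the gap does not at this frame size.
- The generator's deformation model (smoothed Gaussian offsets) has no
  anatomical covariance structure beyond locality; angular-feature
  distributions are plausible but not population-calibrated.
- Elastic landmark mapping is a first-order inverse; at extreme
  α/σ ratios the approximation degrades together with the image
  content itself.
- Nearest-pixel feature lookup makes predictions piecewise-constant
  under sub-pixel image shifts; this is inherent to the
  pixel-difference feature design, not a defect of the port.
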