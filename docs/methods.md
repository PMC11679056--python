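# Methods

## Setting and assumptions

The package models a time-lapse camera-trap deployment: each camera
photographs a fixed scene at regular intervals (hourly by default), in
colour during the day and with an infrared sensor at night.  Three
assumptions shape the design:

1. **The scene is static apart from the targets.**  The temporal mean of
   recent frames is then a usable background estimate; moving objects enter
   it only as faint ghosts diluted by the window length.
2. **Day and night are distinct modalities.**  IR frames are channel-equal
   greyscale with different radiometry, so background windows never mix
   modalities.
3. **Illumination changes are approximately channelwise-linear at the frame
   level.**  A global 3×3 colour mixing absorbs most weather/lighting
   variation between the background window and the current frame; what
   survives the correction is treated as change.

## Background model and difference mask

For frame `n` of modality `L`, the background window is the `count` most
recent frames of modality `L` with index `< n` (default `count = 12`).  The
RGB background is their pixelwise mean; its greyscale flattening uses the
luminosity weights 0.299/0.587/0.114.  All arithmetic is on unit-interval
float64; 8-bit I/O is scaled by 255, which makes every formula scale-free
and clipping well defined.

**Window shortage.**  Early in a sequence fewer than `count` same-modality
priors exist.  The mean generalises to `1/n_sources`, down to
`min_count = 1`; the actual source frames are recorded in the model's
provenance.  This keeps the pipeline total over a sequence instead of
discarding its start.  Below `min_count` a `BackgroundUnavailable` error is
raised, and batch extraction skips the frame with a logged warning.

**Day/night labelling.**  The measured test (max over pixels of
`max(|R−G|, |G−B|) ≤ grey_tolerance`, default 2 on the 0–255 scale) takes
precedence because cameras switch sensors on measured light; the clock rule
(night = [18:00, 06:00), configurable, the window being approximate in the
target deployments) is the fallback for colour frames.

**Colour correction.**  `M` solves the pixels-as-rows least squares
`argmin ‖I − B·M‖²` with no intercept (a pure linear recolouring model).
Degeneracy is declared when the ratio of smallest to largest singular value
of the background pixel matrix falls below 1e-6 — night IR imagery is
exactly rank-1 and would otherwise produce wild matrices — and the identity
is used, flagged, and logged.  Because the identity is always feasible, the
fitted residual never exceeds the uncorrected one; this is asserted as a
test property.  The corrected background is clipped to [0, 1] so the
difference mask stays bounded.  An optional pixel subsample (off by default)
accelerates the fit on large frames without changing the estimator in
expectation.

**Difference mask.**  Mean absolute channel difference between the frame
and the corrected background; values lie in [0, 1] by construction.

**Open choices made.**  Frames containing animals are *not* excluded from
the background window (plain mean; ghosting is diluted by the 12-frame
window).  Feature planes are written as 8-bit PNG; tests that need exact
algebraic identities work on in-memory floats, and the 8-bit quantisation
bound (~1/255 per plane) is respected by the tolerances of the end-to-end
tests.

## Channel stack and augmentation policy

The detector input is `(R, G, B, TA12, DM)`; the RGB planes are never
modified by the feature pipeline.  HSV augmentation applies hue and
saturation gains only to RGB; TA12, being greyscale, receives exactly the
value gain used for RGB (in HSV, `V = max(R,G,B)`, so an unclipped value
gain is the same multiplication); DM is returned bit-identical so the
difference intensity is fully preserved.  Gains act as direct multipliers,
or — when a seed is supplied — as half-ranges for the usual
`1 + U(−1,1)·g` jitter, reproducibly.

## Channel weighting

Both operators scale only TA12 and DM; the RGB planes pass through
bit-identically.

*Fixed:* weights `σ(α)`, `σ(β)` with learnable logits.  The converged values
reported for the target deployment (0.288 for TA12, 0.824 for DM) are used
as a worked example in the tests.

*Modified Squeeze-and-Excitation:* a stem of two 3×3 stride-1 same-padded
convolutions (C→C, C = 5, no bias — the smallest faithful reading, since the
stem's width is not specified in the source design) with an intermediate
ReLU; global average pooling to `z ∈ R⁵`; excitation
`σ(W₂ · relu(W₁ · z)) ∈ (0,1)²`.  Unlike the classic block, exactly two
weights are emitted and applied to the two feature channels of the *input*
stack, leaving RGB untouched.

Training is out of scope.  The operators are deterministic forward passes
with analytic gradients for the scalar test loss `L = Σ` output entries
(gradients reach the parameters only through the two emitted weights), and
`finite_difference_check` validates them against central differences.  The
relative-error denominator is `max(|analytic| + |numeric|, 1)`, the standard
gradcheck convention; with all-zero parameters the excitation is constant
and both sides are exactly zero.  Demo initialisation is a seeded normal;
note that at very small scales (0.05) the ReLU layer can be entirely
inactive for a given input, making all parameter gradients legitimately
zero — tests use scale 0.5, where the network is active and
double-precision central differences agree to ~1e-9.  Sigmoid outputs are
mathematically in (0, 1) but saturate to exact 0/1 in float64 beyond
|logit| ≈ 37; the strict-range invariant therefore holds for any
realistically scaled parameters, and tests stay below saturation.

## Size categories: exact 1-D k-medoids

Box-size strata (small/medium/large) are k-medoids clusters (k = 3) of
normalised box areas — medoids rather than means so the long upper tail of
close-to-camera animals cannot drag the centres.  Rather than the generic
PAM build+swap local search, the 1-D structure is exploited: an optimal
summed-L1 k-medoid solution partitions the *sorted* data into k contiguous
segments whose medoids are segment (lower) medians, found exactly by an
O(k·n²) dynamic program.  The distinction matters: single-swap PAM can stall
one swap short of the global optimum (a 6-point instance exhibiting this is
documented in the development notes), whereas the DP provably matches
exhaustive enumeration — the optimality contract the test suite enforces.
Ties go to the earlier boundary; assignment of a new area goes to the
nearest medoid, ties to the smaller.  The size model is fit once on the full
dataset's areas before partitioning.

## Partition objective and search

Per camera, the statistics are counts (images, boxes per class, boxes per
(class, size), day/night boxes per class); rates are derived views.  Subset
statistics pool member cameras **by totals** (total boxes / total images),
not by averaging camera-level rates, so large cameras weigh proportionally.
The three objective terms are population variances (denominator 3) of the
subset values — a fixed finite set of three subsets, where the population
flavour only rescales the objective; per-class day/night balance uses the
day *fraction* `day/(day+night)` rather than a quotient, which stays defined
for cameras or subsets with zero night boxes (common for small cameras).
Classes absent from any subset are skipped in the day-fraction term with a
logged note.  No cross-term normalisation is applied: the objective is the
raw sum.

The search enumerates all assignments respecting the subset sizes and
forced placements (for ≤ ~15 cameras this is instantaneous; no heuristic
search is provided), rejects any with val or test exceeding
`max_fraction` (default 25%) of all images, and returns the feasible
minimum.  Enumeration order is lexicographic in the sorted camera tuples,
which fixes tie-breaking deterministically; strictly-smaller comparison
keeps the first optimum encountered.

## Synthetic fixtures: the stated world

The scene generator renders a seeded smooth-noise + gradient background,
hourly filename-encoded timestamps (`CAM_YYYYMMDD_HHMMSS.png`, avoiding any
EXIF-writing dependency; the EXIF reading path is tested with a
Pillow-generated JPEG), optional channelwise-linear illumination drift
(linear so the colour-correction recovery property is exact), transient
constant-colour objects with exact change masks and tight bounding boxes,
and night frames rendered exactly channel-equal.

The annotation generator samples, per camera: each image's modality
(Bernoulli `day_image_fraction`), per-class box counts from a
modality-conditional Poisson whose means are chosen so the expected
per-class day fraction of boxes matches the configured target, and
log-normal normalised areas (defaults μ = −5.5, σ = 0.6: areas of order
0.2–1%, the realistic range for animals at camera-trap distances).
Defaults (200 images/camera, ~1 box/image/class, 70% day) mirror the order
of magnitude of real deployments.

Neither generator emulates photorealism, weather, sensor noise, or animal
appearance; green tests establish algebraic and contract correctness of the
pipeline, not field performance of any detector trained on its output.

## Worked-example table

The printed per-camera summary of a 10-camera seabird deployment (4483
annotated images) is embedded as plain text.  It contains image, class, and
day/night counts but not per-box areas, so on this input the size-category
term of the objective is identically zero and the exhaustive search can
(and does) find assignments scoring below the published one, which was
optimised with the size term present.  The bookkeeping reproduction —
subset image totals 3080/589/814 under the 25% cap, 756 candidates with six
train/two val/two test cameras and one forced placement — is the
acceptance-checked quantity.

## Known limitations

- The background mean ghosts slow-moving or long-staying animals into TA12;
  no masking or robust (median) alternative is provided.
- Colour correction is global and linear; localised lighting (shadows,
  beams) survives into DM by design.
- The exhaustive partition search is exponential in camera count; it is the
  right tool at ≤ 15 cameras and deliberately nothing more.
- `fitness_score` (0.1·mAP@0.5 + 0.9·mAP@0.05:0.95) is provided as the
  model-selection utility; computing mAP itself is out of scope.
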