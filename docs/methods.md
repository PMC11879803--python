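# Methods

## Problem and model

A colony-forming assay (CFA) seeds single leukemic cells in a semi-solid
3D matrix and asks, days later, how many grew into colonies. When the
culture is imaged in brightfield as a Z-stack — the same field at many
focal depths — each physical object (a single cell, a cluster of 2–14
cells, or a colony of ≥ 15 cells) appears on several consecutive slices:
sharp near its own depth, increasingly blurred away from it, and
eventually invisible. Counting unique objects therefore has two stages:

1. **Per-slice detection.** Each slice is searched independently for
   dark blob-like objects, each returned as a bounding box with one of
   four hierarchical labels — *candidate* (out of focus, class not yet
   decidable), *cell*, *cluster*, *colony* — and a confidence.
2. **Z-axis tracking.** The per-slice detections are merged into unique
   2.5D objects by multi-object tracking, with the Z index playing the
   role that time plays in video tracking: the same object drifts
   slightly, blurs in and out of "visibility", and must be re-identified
   across gaps rather than double-counted. A trajectory's final class is
   the maximum of its per-slice labels under
   candidate < cell < cluster < colony, so one sharp look at the object
   decides its class even if most slices saw only a blur.

Counts of unique objects per stack then feed the assay read-outs:
plating efficiency PE = 100 x colonies at the final timepoint / starting
denominator (either cells seeded or single cells observed at the first
timepoint; both supported, `observed_start` is the default since that is
what an automated per-ROI count can actually see), survival fraction
SF = colonies after treatment / (cells seeded x PE), and dose-response
IC50 from cluster+colony totals normalized to the vehicle control.

## Synthetic data generator

No microscope data ships with the package; `synthgen` produces scenes
with the statistical structure the pipeline assumes, so every stage is
testable at desk scale.

- **Geometry.** Default 19 slices at 30 µm spacing (total height =
  n_slices x spacing), 256 x 256 px at 2 µm/px. Objects are uniform
  disks of absorbance 0.55 on a background of 0.85; radius =
  6 µm x sqrt(cell count), so projected area is proportional to the
  number of cell-equivalents.
- **Defocus.** Isotropic Gaussian blur with width
  sigma(dz) = 1 µm + 0.08 x dz; convolution conserves total absorbance,
  so contrast fades as blur spreads. No point-spread-function physics is
  attempted — the model is monotone and sufficient to exercise the
  in-focus/candidate labeling.
- **Ground-truth labels.** Within the in-focus half-depth
  (dof = 20 µm ≥ spacing/2, so every object is sharp on at least one
  slice) a slice gets the object's true class; between dof and the
  visibility half-depth (candidate_depth = 100 µm) it gets *candidate*;
  beyond that, no annotation (objects are still faintly rendered out to
  1.5 x candidate_depth).
- **Separation.** Placement is rejection-sampled so that *visible
  footprints* (rim + blur width at the deepest rendered defocus) stay
  at least 12 µm apart. Separation in the in-focus sense is not enough:
  two objects at different depths with overlapping blurred footprints
  merge into one connected component on intermediate slices and can be
  bridged into a single trajectory — the overlap failure mode real
  assays show, which "well-separated" scenes must exclude by
  construction.
- **Counts.** Cluster sizes are drawn from 3–12 cells and colonies from
  18–30, keeping draws away from the 1/2 and 14/15 class boundaries
  where a one-pixel area error would flip the label; a count of exactly
  15 is a colony, making the partition total.
- **Growth.** Per-cell Bernoulli division per hour with probability
  2^(1/12) − 1, i.e. expected doubling every 12 h, scaled by
  (1 − inhibition(c)); a single cell is then expected to cross the
  15-cell colony threshold around 60 h, matching the observed onset of
  colony formation in untreated assays. Counts never decrease (no death
  process).
- **Dose-response tables.** 4PL (below) evaluated at
  log10(concentration) plus iid Gaussian noise; the default design
  mirrors the assay: 5-point 1:5 dilution series, triplicates, 5% noise.

What the generator does *not* emulate: phase-contrast artifacts, debris,
annotation inconsistency, cell motility, irregular colony morphology,
and density-dependent growth. Passing tests therefore demonstrate the
correctness of the counting/tracking/evaluation machinery, not detector
robustness on real microscopy.

All sampling flows through per-call `numpy.random.Generator` objects
seeded from explicit config fields; there is no global random state.

## Reference detector

The neural detector used in production settings is deliberately out of
scope; any callable mapping an image to a list of `Detection` satisfies
the same contract (an adapter reading precomputed detection files is the
intended substitution point). The shipped reference detector is
classical:

- background flattening (global median by default; local median window
  configurable), Otsu threshold (fixed threshold configurable),
  connected components, minimum area 9 px².
- **Area estimation** uses the *half-peak* pixel count of each
  component: pixels above half the component's peak signal. For a disk
  blurred by a Gaussian narrower than its radius the half-peak contour
  sits at the true rim, making cell-equivalent estimates
  n = round(area / cell_area) nearly independent of threshold level and
  moderate defocus. This matters because the track class is a maximum:
  a single blur-inflated "colony" label on one slice would permanently
  upgrade a cluster.
- **Focus measure**: variance of the discrete Laplacian of the patch on
  the [0, 1] intensity scale after a 0.7 px Gaussian pre-smooth (iid
  sensor noise otherwise dominates the Laplacian). Offset-invariant;
  zero for constant patches; monotonically decreasing in defocus for
  this image model. The in-focus decision threshold (default 0.002) is
  scaled down by n^0.25 because Laplacian energy concentrates on the
  rim, whose pixel share shrinks with object size.
- **Classification**: in focus, by cell-equivalents (1 / 2–14 / ≥ 15);
  out of focus, n ≥ 2 becomes a candidate and n < 2 is dropped (a
  defocused single cell is indistinguishable from noise and cannot seed
  a meaningful candidate). Confidence is the product of a focus margin
  and a size margin (distance of n to the nearest class boundary),
  bounded strictly below 1 — so a confidence threshold of 1.0 provably
  empties the output.

Defaults are exposed configuration, not claims of optimality; `tune`
searches detector and tracker parameters jointly, since tracking quality
depends on what the detector feeds it.

## Tracker

Two-stage IoU association per slice, in the spirit of
ByteTrack/BoT-SORT: detections with confidence ≥ high_conf (0.4) are
assigned to open tracks by globally minimum-cost assignment on
1 − IoU (scipy Hungarian solver), accepting pairs with IoU ≥ 0.3; still
unmatched tracks get a second pass against detections with
0.1 ≤ confidence < 0.4 at IoU ≥ 0.2. Unmatched high-confidence
detections open new tracks; unmatched tracks survive up to max_gap = 3
consecutive misses (staying eligible for re-association, which is what
prevents an object that blurs out mid-stack from being counted twice)
and finish beyond that. Track ids are never reused; ties in assignment
break deterministically, so output is invariant to permutations of
detections within a slice.

Deliberate simplifications: no appearance embeddings, no camera-motion
compensation, and no Kalman filter — the predicted box is the last
observed box. Z-stack scenes are quasi-static (drift has no velocity
structure), and tracking here serves only to merge slices into unique
objects; a `predict` hook accepts any motion model.

Known failure mode, reproduced in tests: an object absent longer than
max_gap splits into two trajectories and is overcounted — the same
error mode large colonies spanning many focal planes cause in practice.

## Evaluation

- **Identity measures** (IDF1/IDP/IDR): one global minimum-cost
  bipartite matching between whole ground-truth and hypothesis
  trajectories, with dummy partners, maximizing total frame matches
  (frames where boxes overlap at IoU ≥ 0.5). IDTP is the achieved
  maximum; IDFN/IDFP are leftover GT/hypothesis frames;
  IDF1 = 2·IDTP / (2·IDTP + IDFP + IDFN). Verified in tests against an
  exhaustive enumeration of all trajectory pairings on instances with
  ≤ 5 tracks per side.
- **Coverage and ID switches** use CLEAR-style sequential per-frame
  matching that keeps the previous frame's assignment whenever it still
  overlaps. Coverage ratio r ≥ 0.8 → mostly tracked, r ≤ 0.2 → mostly
  lost, else partially tracked (boundary conventions of the standard
  MOT toolchain; the verbal definitions "more than 80% / less than 20%"
  leave the boundary itself open). An ID switch is an event where a GT
  object's matched hypothesis id changes between consecutive matched
  frames.
- **Detector evaluation**: per-class AP at IoU 0.5 with confidence-
  ranked greedy matching (each GT consumed once) and all-point
  interpolation of the precision-recall curve; mAP50 is the unweighted
  mean over classes with ground truth. The confusion matrix assigns
  each detection to its best-IoU ground-truth class regardless of
  class, or to background; unmatched GT fills the background row.
- **Summaries** average per-dataset score columns arithmetically;
  percentage shares (e.g. the mostly-tracked share) are derived from
  the *averaged counts*, which is the only convention that reproduces
  the published summary percentages. Unrounded means are always
  emitted alongside half-up rounded display columns, because printed
  tables round inconsistently (the all-class IDF1 average 0.7525 prints
  as 0.752, and the mostly-lost share differs in the last digit from
  100 − MT% − PT%).
- **Objective**: IDF1 x (MT + PT)/n_objects, the joint target for
  hyperparameter search — the tracked-fraction factor deliberately
  emphasizes recall of unique objects. `tune` is a seeded uniform
  random search over box/integer/choice dimensions with a pluggable
  sampler hook; given a deterministic evaluation it is reproducible
  bit-for-bit.

## Dose-response

Responses are per-replicate cluster+colony totals divided by the vehicle
control mean (control maps to 1.0; the scale is a fraction, and the
linear-model crossing level of 0.5 is configurable). The primary model
is the four-parameter logistic in the inhibitor form

    y = bottom + (top − bottom) / (1 + 10^((x − logIC50)·hill)),

x = log10(concentration in nM): with hill > 0 the response falls from
`top` at zero dose to `bottom`, and IC50 = 10^logIC50. Fitting is plain
least squares (`scipy.optimize.curve_fit`) with self-starting values
(top = max response, bottom = min, logIC50 = median x, hill = 1);
parameters are unconstrained by default, with optional equality
constraints (e.g. top = 1). At least 4 distinct concentrations are
required; otherwise, or on non-convergence, `select_and_fit` falls back
to ordinary least squares of response on x and solves the line for the
0.5 crossing, recording the fallback. No robustification or outlier
down-weighting is applied.

At the assay's design (5-point 1:5 dilutions, triplicates, 5% noise),
100 seeded simulations recover logIC50 with median absolute error below
0.06 and land within 2-fold of truth in every run; noiseless recovery is
exact to < 1e-6 in logIC50.

## Problem sizes and determinism

The test suite and acceptance script use 256 px scenes of 10 objects
over 19 slices (≈ 0.1 s per full pipeline run), 10–20 seeded scenarios
per property, and 100-replicate Monte-Carlo studies; the whole suite
runs in a few seconds. Brute-force oracles are limited to ≤ 6x6
assignment instances and ≤ 5 trajectories per side, where exhaustive
enumeration is cheap. Every stochastic quantity is reproducible from a
single integer seed.

## Known limitations

- The reference detector is tuned to the synthetic image model; on real
  brightfield data a learned detector behind the same interface is the
  expected configuration.
- Candidate-only trajectories are retained by the tracker and excluded
  only at counting time; a real out-of-focus object that never sharpens
  is invisible to the class tallies by design.
- The growth model has no cell death, motility, or crowding; dose
  response enters only through the division probability.
- MOTA/MOTP/HOTA composites and the mAP 50–95 sweep are not
  implemented; evaluation is single-threshold.
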