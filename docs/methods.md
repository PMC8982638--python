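# Methods

## Scope and data model

`mbassay` analyzes single-animal marble-burying sessions recorded top-down.
The pipeline is track → per-frame features → frame classification → bout
segmentation → activity/topography, plus an independent image-based marble
coverage scorer and the agreement/group statistics used to validate
classifier output against human annotation. All per-frame state lives in
two aligned structures: the **track** (a DataFrame with `frame, t_s, x_px,
y_px, major_px, minor_px, theta_rad, valid`) and the **label series**
(per-frame score and ternary label positive/negative/unannotated).
Coordinates are pixel-centered, 0-based, origin top-left; orientation is
the body-axis angle from +x reduced to [0, π) (no head/tail polarity).
Conversion to centimeters happens only in the activity module, via the
arena calibration.

## Tracking

Background is the per-pixel median of a strided frame sample; it is valid
only when the animal is absent from each pixel in more than half of the
sampled frames — true for full-length sessions, and something short test
clips must respect by construction. Each frame is segmented by thresholding
the absolute difference against the background (Otsu per frame by default; a
fixed threshold is available for flicker-free recordings). The largest
connected component at or above `min_area_px` (default 20) is taken as the
animal — single-animal assumption, ties broken by label scan order — and
its centroid, axis lengths (4·√eigenvalue of the pixel covariance, the
uniform-ellipse convention) and orientation (½·atan2(2μ₁₁, μ₂₀−μ₀₂)) come
from second-order moments. Frames with no qualifying component are invalid;
runs of at most `max_gap_frames` (default 5) invalid frames bounded by valid
ones are linearly interpolated, orientation through its doubled-angle
vector. Dark-animal-on-light-bedding polarity is assumed (black-6 mice on
wood-chip bedding); positions are body centroids throughout — nose position
is out of scope.

Calibration averages the top-edge and left-edge px/cm estimates from the
four arena corner points and warns when they disagree by more than 5%.

## Frame classification

Per-frame features: speed, acceleration and turn rate by central
differences on the valid track; ellipse area and aspect; distance to the
nearest wall and nearest corner; and, when raw frames are available, the
mean absolute frame-to-frame intensity change in a 30-px disk around the
centroid. Each base feature is expanded into centered sliding-window
statistics — mean, population σ, min, max, end-minus-start — at radii
{2, 6, 12} frames (0.08–0.5 s at 25 fps), truncated at the series edges,
NaN-skipping. Missing values (invalid frames, absent pixel-change channel)
are left as NaN.

The classifier is a boosted ensemble of depth-≤2 trees, 100 rounds
(`HistGradientBoostingClassifier`), chosen as the nearest open analog of
GentleBoost-style behavior classifiers; it handles NaN features natively
and is deterministic under a fixed seed. Class weights are balanced:
annotation for this assay is selective rather than exhaustive, so the
annotated class mix is an artifact of the annotator, not of the behavior.
Unannotated frames are excluded from training. The decision threshold is 0
on the ensemble margin; predicted binary labels (not scores) are optionally
median-smoothed (radius 2 frames by default), with ties keeping the raw
label.

Cross-validation folds are **contiguous blocks of same-label segments**
with approximately equal annotated-frame counts. Two alternatives were
rejected: shuffled frame-level folds leak temporal information (adjacent
frames are near-duplicates under window features), and interleaved
(round-robin) segment folds systematically bias chance-level accuracy
*below* 0.5, because a test segment's temporal neighbors always carry the
opposite label (runs alternate) and sit in the training side. Reported
accuracies are per class, pooled over folds: TP/(TP+FN) for burying,
TN/(TN+FP) for non-burying.

A calibration caveat: even with block folds, chance-level per-class
accuracy under label shuffling is not frame-binomial. Each fold's model
carries a small net margin offset from fitting boosting rounds to noise,
shifting that fold's positive-prediction rate coherently; measured spread
is ≈1.5× the binomial standard deviation and this ratio is invariant to
session length. Chance-level estimates should therefore be read with
segment/fold-level error bars, not per-frame ones.

## Bout segmentation

Bouts are maximal runs of positive frames as half-open frame intervals.
Runs separated by at most `max_gap_s` of negative frames are merged first
(default 0 — no bridging), then merged runs shorter than `min_bout_s`
(default 1.0 s, the conventional minimum for burying analysis) are dropped.
Merge-before-drop matters: dropping first could erase fragments of one long
bout split by single-frame classifier flicker. Durations come from frame
counts divided by fps, never from float timestamps. Totals (and the
cumulative 60-s-binned curve) are computed on the post-filter mask, so the
curve's final value always equals the summary's total burying time; whether
totals should be pre- or post-filter is genuinely open, and post-filter was
chosen for internal consistency.

## Activity and topography

Distance is the sum of Euclidean steps between consecutive valid frames in
cm; steps above `max_step_cm` (default 10 cm/frame, physically implausible
at 25 fps) are excluded as tracking glitches and counted. Mean speed is
distance over the time spanned by included steps. Heatmaps are raw count
grids (default 16-px bins — the bin size is a declared choice, not a
reproduction) split by label; burying + non-burying counts always equal the
number of valid frames. Corner preference is the fraction of valid frames
inside four corner squares of side `corner_frac · min(arena dims)`
(default 0.25).

## Marble coverage

Marbles are segmented in HSV space (shipped blue range H ∈ [0.50, 0.75],
S ≥ 0.25, V ≥ 0.15, all tunable — marble and bedding colors vary across
setups), connected components filtered by area and ordered row-major, with
rows found by gap-clustering centroid rows (a mostly-covered marble's
visible sliver shifts its centroid by up to a radius). Coverage is
clamp(1 − visible/baseline, 0, 1); the baseline is a pre-test photograph
when available, a supplied disk area, or — fallback — the median detected
area, which is only sound when most marbles are uncovered. When an expected
count is supplied, undetected marbles enter the report as fully buried.
Default burial threshold is 2/3, the stricter of the two literature
conventions; 0.5 is the other, both exposed. Method comparison uses
Spearman rank correlation with an exact permutation null (full n!
enumeration) for n ≤ 8.

## Agreement and group statistics

Frame agreement is the 2×2 confusion over jointly annotated frames, plus
the positives ratio of series a over series b. Group comparisons follow the
gated procedure standard in this literature: each group (or the paired
differences) is tested for normality at α = 0.05 — D'Agostino–Pearson by
default, Shapiro–Wilk for paired pharmacology designs, and samples too
small for the chosen test (n < 8 for D'Agostino–Pearson) are routed to the
rank branch. Both groups must pass for the parametric branch (the gate's
resolution of disagreement between groups is a declared choice). Rank tests
use the exactly enumerated null when the combined n ≤ 12 and the normal
approximation with continuity correction above that. One- versus two-tailed
is always the caller's decision. Gated procedures are known to be only
approximately size-α; the empirical type-I error at n = 12 per group
(normal data for the parametric branch, exponential for the rank branch)
measures within [0.035, 0.065] at α = 0.05.

## Synthetic data

The generator emulates the standard session: 26.6 × 42.5 cm arena at
10 px/cm, 25 fps, defaults of 30 min, 20 bouts of 8 ± 4 s, mean speed
6 cm/s, corner bias 0.8. The walk is an Ornstein–Uhlenbeck velocity process
(relaxation time 0.5 s, per-axis σ set so the stationary mean speed matches
the requested value) with reflecting walls keeping the 6 × 3 cm body
ellipse inside the arena. Each bout has an anchor — a corner-zone center
(zones are squares of side min-dim/4) with probability `corner_bias`, else
a random interior point; during the preceding rest gap (up to 5 s) the
animal travels to the anchor at normal speed, and during the bout its speed
is capped at 20% of the session mean with a weak spring toward the anchor.
Bout durations are normal, truncated positive; bouts are separated by at
least 1 s, so re-segmentation of the true labels reproduces them exactly.
Rendered frames are a fixed smooth bedding texture (intensity ≈ 200) with a
uniform dark ellipse (intensity 60) and optional Gaussian pixel noise.
Marble images draw blue disks (radius 20 px, five per row) on noisy
bedding-colored background and occlude each with a bedding-colored circular
segment whose chord offset is solved from the requested area fraction;
the true visible pixel count per marble is returned. Observer noise flips
each frame independently (miss and false-alarm rates). Feature tables are
Gaussian with the full class-mean shift on one known axis.

What the generator does **not** emulate — and what passing tests therefore
do not show: photorealistic mouse appearance and posture, bedding
displacement and its visual texture change, marbles being buried and
unburied over time, multi-animal scenes, lighting drift, and any
relationship between true burying kinematics and the low-speed/corner model
beyond the declared one. The paper-scale reference numbers for classifier
accuracy on real video (≈83% per class) depend on real recordings and
annotations and are documentation references, not targets of this package's
tests.

## Problem sizes in tests and verification

The test suite and `scripts/acceptance.py` use scaled sessions chosen to
keep every property measurable with comfortable margins: 1000-frame random
label series (×200) for the segmentation oracle; 120-s sessions (×20) for
exact parameter recovery; 500-frame noise-free free-roaming stacks (×10)
for tracker accuracy — free-roaming because the median-background
precondition must hold inside a short clip just as it does over a full
session; 120-s balanced sessions (×10) for CV accuracy at separation 3 and
240-s ones for chance-level behavior (where the binomial band dominates
fold-level variance); 20-marble images across six coverage levels (×10
seeds); 2000 null pairs per branch at n = 12 per group for the gate's
empirical size.

## Known limitations

Single animal only; body-centroid positions (no nose/limb pose); no marble
tracking through the video; no multiple-testing correction across metrics
(deliberately, matching field practice for this assay); MP4/AVI decoding
requires an imageio ffmpeg backend — PNG frame directories are the
first-class input; the median-baseline fallback in coverage scoring biases
coverage downward when most marbles are buried.
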