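# Methods

This note documents the models, conventions and numerical choices behind
`vmtrack`, and what the synthetic-data tests do and do not establish about
real tracking data.

## Data model and conventions

A `PoseTrack` is a dense `(frames, individuals, bodyparts, 2)` float array of
image-pixel coordinates: origin top-left, x rightward, y downward, frames
0-based. A missing keypoint is NaN in both coordinates — never half-missing —
and optional per-keypoint confidence is NaN wherever the keypoint is missing.
No confidence-based filtering is applied on read; an optional threshold
(default off) can blank low-confidence points, since the evaluation framework
itself defines no likelihood cutoff.

Flat single-animal tables (one column block per body part) are mapped to
multi-animal form by an individual-major convention: body parts
`m1_nose … m1_tail, m2_nose, …` split into per-individual blocks, with the
common `<prefix>_` stripped from part names when that yields unique labels.
CSV round trips are bit-exact (`float_precision="round_trip"` on read); HDF5
stores the same pandas frame.

## Identity pairing

Predicted and GT individuals are paired **once per scene** by minimum-cost
one-to-one assignment. The cost of a (predicted, GT) pair is the *mean*
Euclidean distance over all (frame, bodypart) cells observed on both sides —
mean rather than sum so pairs with more co-observed cells are not penalized;
pairs with no co-observed cell get a cost one larger than the largest
observed cost. Scene-global pairing is deliberate: per-frame re-pairing would
silently absorb the identity switches the framework exists to expose.

The assignment itself is `scipy.optimize.linear_sum_assignment`, wrapped with
a lexicographic refinement: each row in turn is pinned to the smallest column
index that still admits an optimal completion (verified by re-solving the
reduced problem), so exact cost ties resolve deterministically to the lowest
(predicted, GT) index pair. When predictions outnumber GT individuals the
extras stay unassigned and surface only as FPs.

## Verdict taxonomy

Thresholds compare with `distance <= τ` ("within"); the boundary case has
measure zero on real data. τ defaults to 10 px for keypoints and 20 px for
centroids. For each annotated GT cell:

1. missing prediction → FN;
2. within τ of the corresponding GT keypoint → MATCH, even when another GT
   keypoint is nearer (the corresponding GT takes priority);
3. otherwise the nearest annotated GT keypoint within τ decides the FP
   subtype — same body part / different identity → ID-mismatch FP, different
   body part (any identity) → bodypart-mismatch FP — with exact distance
   ties broken by (identity index, body-part index);
4. within τ of nothing → deviating FP.

ID switches: per (GT individual, body part) cell series in frame order, a
verdict carrying a matched GT identity (MATCH or either mismatch FP) is a
switch when that identity differs from the most recent earlier matched
identity; FN and deviating frames are skipped when looking back, however long
the gap, and a cell's first matched frame is never a switch. The carry-forward
state resets at scene start, which is why switch evaluation requires
consecutive frames.

Summary denominators: GT-denominated percentages (Tgt match, FN, FP and
subtypes, ID switches) divide by the number of annotated GT cells;
prediction-denominated ones (Pred match, Bodypart match = Match +
ID-mismatch FP) divide by the number of non-missing predictions. RMSE is
taken over all non-missing predictions with an annotated corresponding GT —
i.e., MATCH plus every FP subtype — because it is a prediction-based metric
measured to the *corresponding* GT; `rmse_matches_only=True` restricts it to
matches for sensitivity analyses. Cells with missing GT are excluded from
every denominator.

The centroid variant averages the designated predicted parts (all, by
default; a single available part is itself the centroid; none → centroid FN)
and matches within 20 px of **any** of the GT individual's axis parts
(default: the 3 central chain parts). Body-part categories, switches and RMSE
do not apply to centroids.

## Virtual-marker accuracy

A marker's ID matches when it lies within 10 px of *any* same-individual GT
keypoint; a missing marker counts against `id_matched_vm_pct`, whose
denominator is the expected marker count (2 × animals × frames). The
marker-to-individual correspondence is declared (config map or label
identity), not inferred. Per animal-frame, the two marker statuses collapse
into six patterns (both match / one of two / neither / single present
matching / single present not matching / both missing) whose scene
proportions sum to 1 by construction.

## Group metrics

* **Adjacent-distance variance** — population variance (ddof 0) of the n−1
  distances along the ordered body chain; any missing chain point makes the
  frame's statistic missing. Equidistant chains give exactly 0.
* **IQR outliers** — fence = Q3 + 1.5·IQR of a pooled reference (conditions
  are pooled so both are judged against one threshold), linear-interpolation
  (type-7) quantiles, upper fence only: only inflated variance signals
  tracking failure.
* **Headings** — angle of (anterior − second) keypoint in (−π, π],
  mathematical convention on raw pixel coordinates. The image y-axis points
  down, but every downstream quantity is a *difference* of angles and is
  therefore flip-invariant.
* **Group cosine similarity** — mean of cos(θi − θj) over all unordered
  pairs with observed headings; missing-heading individuals are dropped per
  frame, and fewer than two observed headings yield a missing value.
* **Heading flips** — consecutive-frame angular differences wrapped to
  [0, π]; strictly greater than 90° counts as abnormal; pairs touching a
  missing heading are skipped, not bridged.
* **Pose similarity** — per individual-frame, the pairwise keypoint distance
  matrix with its upper triangle z-scored (population sd) — invariant to
  rigid motion and uniform scale, so dancers of different apparent size
  compare fairly; degenerate poses (all distances equal, sd ≲ 1e-9 relative)
  are rejected. Pose RMSD between two individuals is the RMS difference over
  co-present upper-triangle entries; the frame score is the mean over all
  unordered pairs.
* **Overlap** — same-named keypoints of two individuals overlap when their
  distance is *strictly below* the threshold (default 10 px); frames with
  either keypoint missing leave both numerator and denominator.

## Synthetic data

The generator emulates the geometry the evaluation targets: each animal is a
straight chain of equidistant keypoints along its body axis whose head
performs a heading random walk (wrapped Gaussian turn increments, Gaussian
speed clipped at 0) inside an inner box inset by the chain length, with
reflective boundaries, so adjacent distances equal the configured spacing
exactly and the chain never leaves the arena. Defaults describe a mouse-like
scene — 3 animals × 6 midline keypoints, 300 consecutive frames, 640×480 px
arena, 15 px spacing, speed 4 ± 2 px/frame, turn sd 0.3 rad/frame — and
`fish_school_config()` gives the 10-fish × 5-keypoint school (50 keypoint
series per frame). Speeds and turn rates are round numbers chosen to produce
visually plausible rodent/fish motion at 30 fps; no empirical motion model is
claimed.

`inject_errors` degrades a clean track in a fixed order — jitter → body-part
swap → deviating displacement → FN deletion → ID swap — with FN and deviating
drawn from one uniform variate per cell so a cell receives at most one of the
two; deviating displacements are uniform on a ring whose inner radius must
exceed the evaluation threshold (default 30–50 px against τ = 10), so a
displaced detection can never classify as a match. Discrete corruptions are
logged per cell, ID swaps per episode together with the per-frame
true-identity map; jitter is a global noise field recorded by its sd rather
than per cell (a per-cell jitter log would add nothing beyond the sd and
seed). Trajectory and error seeds are independent so one ground truth can be
degraded many ways for paired designs.

What the simulator does **not** model: occlusion geometry (errors are
i.i.d. across cells rather than clustered in crowding events), body bending,
detector confidence structure, and social interaction. Passing the synthetic
checks therefore validates the *bookkeeping* — verdict logic, denominators,
switch carry-forward, metric identities — not any claim about how a
particular tracker performs on real video.

## Verification design

Closed forms used as oracles: under pure isotropic jitter of sd σ the
keypoint displacement is Rayleigh, so P(match) = 1 − exp(−τ²/2σ²) (0.8647 at
σ = 5, τ = 10, checked within a 3-sigma binomial band at n = 25,000) and
RMSE → σ√2 (7.071 px, checked within 2 %). Injected FN and deviating rates
must be recovered *exactly* against the error log; the deviating check uses a
single animal with 60 px chain spacing so a 30–50 px displacement can never
land within 10 px of any GT keypoint. ID-swap recovery uses two parallel
chains 400 px apart, making every in-episode cell an ID-mismatch FP and
putting switch onsets exactly at the episode's start and end frames. The
verdict engine is additionally checked cell-for-cell against an independent
nested-loop classifier on randomized scenes, and the Hungarian solver against
exhaustive permutation search up to 6×6.

The directional school comparison degrades one condition with baseline 2 px
jitter plus 5 % body-part swaps and 5 % FNs: jitter moves the median
adjacent-distance variance off the clean condition's zero, while swaps and
FNs drive the outlier-frame and heading-flip excesses; all three must be
strictly worse than clean.

Problem sizes in the test suite and acceptance script (100 randomized scenes
for oracle agreement, 1,000 for conservation and assignment optimality,
25,000 keypoints for the closed forms, 600–800-frame recovery scenes) keep a
full run in the low seconds while leaving every statistical band comfortably
resolvable.

## Rendering and cleaning

`delete_range`/`keep_only` rewrite only the targeted cells (everything else
is bit-identical) and are idempotent; time ranges convert conservatively as
start = ⌊t₀·fps⌋, end = ⌈t₁·fps⌉ − 1 inclusive. Rendering draws filled discs
at integer-rounded centers with anti-aliasing off, so pixel-level assertions
are exact; palettes are explicit RGB lists (documented approximations of the
pose-tool palettes, not tied to a plotting library). Frames move as uint8
stacks or lossless PNG sequence directories via imageio; compressed-video
decoding is out of scope of the test fixtures, which are lossless by design.

## Known limitations

* Scene-global pairing assumes the prediction tracks the same animal for the
  majority of the scene; a tracker swapped for >50 % of frames would be
  paired to the swapped identity and scored accordingly.
* The ID-switch count is per cell, not per event: a swap episode of one
  animal with k body parts contributes k onset flags (and k more when it
  reverts), matching the GT-keypoint-denominated switch percentage.
* The IQR fence is meaningful only when the pooled reference mixes the
  conditions being compared; per-condition fences would not be comparable.
* `solve_assignment`'s lexicographic tie refinement costs O(n²) extra solver
  calls; negligible at animal-group sizes, not intended for hundreds of rows.
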