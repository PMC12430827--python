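# Methods

This note documents the models, conventions and numerical choices behind
surgikit, and what the synthetic test bed does and does not establish.

## Detection evaluation

**Matching model.** Detections and ground truth are matched per frame and
per class. Detections are processed in descending confidence order; each
takes the unmatched same-class ground-truth box of highest IoU, and the
match is accepted iff IoU strictly exceeds the threshold (default 0.3).
Matching is one-to-one: a second detection over an already-matched box
becomes an FP. Cross-class overlap never matches, so class confusion at a
correct location costs one FN (true class) plus one FP (predicted class).
The greedy order is the standard convention in detection evaluation; it is
not guaranteed to maximize TP in adversarial geometry (a detection
overlapping two ground-truth boxes above threshold while a second
detection overlaps only one of them), but such geometry requires
same-class ground-truth boxes in near-contact, which framewise annotation
of physically distinct instruments does not produce. The test suite
checks equivalence against an exhaustive optimal-assignment oracle on
1000 random detector-like frames.

**Accumulation.** TP/FP/FN are accumulated over the whole evaluated set
per class before the precision/sensitivity/F1 formulas are applied (one
number per class, not per-frame averages). A class with no detections has
undefined precision; a class with no ground truth has undefined
sensitivity. Undefined values are `None`, never coerced to zero, and
excluded from macro averages — important when an evaluation set lacks
some instrument classes entirely.

**Aggregation.** Two macro F1 conventions coexist in published summary
tables and differ in general; both are computed and named explicitly
(`macro_f1_of_means` vs `macro_mean_f1`). No dominance relation between
them is assumed. "mAP" here is the unweighted mean of per-class
precisions; PR-curve AP at swept thresholds is deliberately out of scope.

## Detector post-processing contracts

- Confidence filter is strict (`score > 0.2` by default): a score exactly
  at the threshold is rejected. The threshold is configurable.
- NMS is classic greedy, per class, IoU threshold 0.3: suppression never
  crosses classes, because cross-class duplicate predictions are a failure
  mode evaluation must observe, not an artifact to remove. Tie-breaks on
  equal confidence (class id, then box corners) make the result
  deterministic and the operation idempotent.
- Letterbox geometry: scale = min(960/w, 544/h); scaled dimensions are
  rounded half-away-from-zero and clamped to the target; zero padding
  fills the right and bottom margins only. Whether a real pipeline rounds
  or floors the scaled size is not observable from the target geometry
  alone; rounding was chosen and the common source resolutions
  (1920×1080 → pad-bottom 4; 720×576 → pad-right 280; 720×480 →
  pad-right 144) are frozen as test cases.
- Pixel standardization is the affine map (v − mean)/std per RGB channel
  with the conventional ImageNet-derived constants; it is exactly
  invertible given the config.

## Trajectories and kinematics

Centroids of post-processed, class-filtered detections form one
trajectory per instrument class per video; only *successive* frames are
linked, so detection gaps contribute no path (no interpolation) while the
trajectory continues after the gap. If a frame carries several same-class
boxes, the highest-confidence one is taken (ties: nearest to the previous
point, then lowest x) — adequate because the analyzed task has exactly
one physical instrument per class, and documented as a limitation
otherwise.

Moving time counts trajectory *points* (frames with a detection), so a
single detected frame yields moving time 1 and velocity 0. Velocities are
px/frame; multiply by fps for px/s. Stitch windows are half-open
`[start, end)` frame intervals supplied externally (needle–tissue contact
is a manual judgment); windowing is applied before metric computation,
and a segment whose endpoints straddle a boundary belongs to neither
stitch. Empty per-stitch trajectories produce no kinematics row rather
than zeros.

## Skill assessment

GOALS scoring uses four facets (depth perception, bimanual dexterity,
efficiency, tissue handling; autonomy omitted as unjudgeable from video),
1–5 each, totalled per rater (range 4–20) and averaged across raters.
The proficiency cutoff is 12 with `mean >= cutoff → proficient`; the
boundary convention is explicit and configurable because a mean of
exactly 12 is otherwise ambiguous.

Metrics are described as median (IQR) with quartiles by linear
interpolation (numpy's default; the convention is configurable since
software packages differ). Groups are compared with the two-sided
Mann–Whitney U test: U from midranks, exact permutation null for
tie-free samples with n ≤ 12, otherwise normal approximation with
tie-corrected variance and continuity correction; a fully degenerate
input (all values identical) returns p = 1 with a flag. Stitches are
treated as independent observations — the within-video clustering this
ignores would require mixed models, which are out of scope; the
comparison report carries the number of tests performed and applies no
multiplicity correction.

## Synthetic data: what it emulates

**Detector errors** are independent per box and frame: per-class miss
probability, Poisson spurious boxes (uniform position, sizes resampled
from the ground-truth range so spurious boxes are not trivially
separable), row-stochastic class confusion, Gaussian corner jitter, and
Beta-distributed confidences (Beta(8,2) for true detections, Beta(2,4)
for spurious ones) so confidence thresholds bite realistically. Real
detector errors are temporally correlated (fog, blur, occlusion persist
across frames); this generator does not model that, so passing tests
establish correctness of the measurement arithmetic, not robustness to
correlated failure bursts.

**Suturing sessions** move two instruments with an EMA-smoothed heading
and per-frame step magnitude max(0, N(step, sd)), reflecting off the
image margins. With zero noise a T-frame stitch has path exactly
(T−1)·step, which anchors the closed-form tests. The skill contrast is
carried by stitch duration, step length and step noise:

| group          | frames/stitch | step (px/frame) | step noise sd |
|----------------|---------------|-----------------|---------------|
| proficient     | N(90, 20)     | 6.0             | 1.5           |
| non-proficient | N(160, 35)    | 4.5             | 3.0           |

chosen once so that the proficient group has shorter paths
(~534 px vs ~716 px expected), shorter moving times and higher
velocities — the direction observed in real suturing — with overlap
large enough that the comparison is a statistical question rather than a
foregone conclusion per stitch. Stitch durations are desk-scale (a few
seconds of video) to keep full-cohort simulations cheap; the default
cohort is 7 proficient + 4 non-proficient videos totalling 62 and 28
stitches, matching the group sizes of the motivating setting. Simulated
GOALS facet scores are drawn in 4–5 (proficient) or 1–2 (non-proficient),
so labelling recovers the generating group by construction; the
simulation exercises the labelling arithmetic, not rater behavior.

All generators are bit-reproducible given a seed.

## Numerical and interface choices

- Boxes are continuous corner coordinates; area is width×height with no
  +1 correction, so IoU is scale-free and COCO-compatible.
- Frame indices are 0-based throughout.
- The 12→10 instrument-class consolidation ships as a default `LabelSet`
  (data, not code) and is fully overridable.
- COCO "results" lists are accepted for detections alongside full COCO
  files; in the bare-list dialect the image id doubles as the frame index.
- Kinematics CSVs are read with round-trip float parsing so
  write-then-read is the identity.
- The published per-class benchmark table in `surgikit.benchmarks` is an
  *input* (printed percentages) used to verify aggregation arithmetic; the
  package never claims to reproduce the underlying detector runs, which
  would require the original videos and trained weights.

## Known limitations

- 2-D trajectories only; no depth axis, and camera-distance variation
  between videos is not modelled or corrected.
- No identity tracking: two simultaneous same-class instruments would be
  conflated.
- Automatic stitch-boundary detection is out of scope; windows are manual
  inputs.
- Group comparison treats stitches as exchangeable across videos within a
  group.
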