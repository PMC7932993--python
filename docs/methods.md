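# Methods

## Data model

The unit of analysis is a *clip*: an ordered sequence of video frames to
each of which a pose estimator has fit a fixed keypoint skeleton. Supported
skeletons are the three standard 2-D models — `body25` (25 body points),
`face` (70 points), and `hand_left`/`hand_right` (21 points each). Every
keypoint observation is a triplet `(x, y, c)`: pixel coordinates in image
convention (origin top-left, y increasing downward; never flipped at the
I/O layer) and a detection confidence in [0, 1]. The triplet `(0, 0, 0)` is
the estimator's convention for a failed fit and is treated as missing data,
not as a position.

A clip on disk is either a directory of per-frame JSON files (the
estimator's native output, one `people` array per document with flat
`[x0, y0, c0, ...]` keypoint arrays) or a single CSV table with one row per
frame and interleaved per-point columns `x0, y0, c0, x1, y1, c1, ...`. The
interleaved order mirrors the flat JSON arrays; a one-line `#` comment
ahead of the header carries model name, frame rate, and clip id so the
round trip is lossless including fps. All floats are serialized at full
precision (`%.17g`) and parsed with round-trip-exact float conversion, so
write→read is the identity and re-runs are byte-reproducible.

When several people appear in a frame, one is selected by a person policy:
`first` (array order, the default), `highest_mean_confidence`, or
`error_if_multiple` for corpora where a second detection indicates a
problem. Frame order comes from the numeric suffix of each filename, never
from directory order; a gap in the frame numbering is an error by default
(optionally filled with all-zero frames).

## Cleaning

An observation is invalid iff it is an all-zero triplet or its confidence
is *strictly* below the cutoff (default 0.3; `c = 0.30` is kept,
`c = 0.29` is imputed). Invalid x/y cells are replaced per point by linear
interpolation over frame index between the nearest valid frames; an
isolated gap therefore gets the mean of its two neighbours, and a run of
invalid frames lies on the straight line between the bounding valid
frames. Runs touching a clip boundary take the nearest valid value
(constant fill). A point with no valid observation anywhere in the clip
cannot be imputed and raises an error naming the point.

Two consequences drive the test suite: linear interpolation reproduces
*affine* trajectories exactly regardless of the interior dropout pattern,
and cleaning is idempotent on values. Confidences are deliberately never
rewritten — the validity mask is returned alongside the cleaned sequence
as provenance, so downstream code can still tell imputed cells apart.
Cleaning does no smoothing and no outlier detection beyond these two
rules; a plausible-looking but wrong high-confidence fit passes through
untouched.

## Kinematics and the MF1 series

Velocity is the first frame difference divided by the frame interval
`Δt = 1/fps`, expressed in pixels/second; acceleration is the first
difference of velocity (pixels/second²). A clip of `n` frames yields
`n−1` velocity rows and `n−2` acceleration rows; no padding row is
prepended. The frame rate defaults to 25 fps and must be set explicitly
for material recorded at other rates — all velocities scale linearly with
fps, so a wrong rate scales every motion value by the same factor.

The per-transition motion scalar sums the per-point vectors first, then
takes the Euclidean norm: `MF1_t = ||Σᵢ v_{t,i}||`. The order matters:
equal-and-opposite motions cancel (two hands converging symmetrically
contribute nothing), which is the defined semantics of the measure. Where
that cancellation is undesirable the `sum_of_norms` variant (`Σᵢ ||v_i||`,
an upper bound by the triangle inequality) is exposed under its own name
and is never the default. Both per-transition series and per-clip
statistics (sum, mean, peak, argmax) are provided; the sum is the headline
scalar for matching clips across conditions.

The time axis assigns transition `t → t+1` the timestamp of its later
frame, `(t+1)/fps`, so a 125-frame clip at 25 fps spans 0.04–4.96 s.

## Movement-segment detection

`detect_motion_segments` flags candidate movement episodes: transitions
whose MF1 exceeds `threshold_frac` (default 0.1) of the series maximum,
with active runs merged when separated by fewer than `min_len` (default 3)
quiet transitions and discarded when shorter than `min_len`. The relative
threshold makes the rule amplitude-invariant but also means an all-but-
static clip will still segment its largest wiggle; the defaults are a
pragmatic convenience for screening sign onset/offset, not a validated
onset-detection algorithm, and results should be inspected against the
plotted series.

## Arm laterality

`det_hand` classifies which arm moved, on `body25` only. Each side's
motion is the summed speed `√(vx² + vy²)` over all transitions of its
shoulder–elbow–wrist keypoints (right: indices 2, 3, 4; left: 5, 6, 7;
labels are anatomical, so the actor's right arm is on the image's left).
The label is `none` when both sides fall below an absolute floor (default
1 px/s summed — effectively "no motion at all" at typical resolutions),
`both` when min/max ≥ `rel_threshold` (default 0.5), otherwise the busier
side. The rule, keypoint subset, and both constants are this package's own
design decisions; they are configurable, and no bit-compatibility with any
other implementation is claimed. Wrist-only or hand-model laterality is
out of scope.

## Video metadata

Technical metadata (duration, fps, frame count, resolution, codec) comes
from an external probe binary invoked through a pinned subprocess
contract: `ffprobe -v error -print_format json -show_format -show_streams
<file>`, parsed from the JSON `format`/`streams` sections. Any executable
honouring that contract can be substituted (`probe_cmd=`); the test suite
uses a generated stub probe plus synthetic stub clip files, which
exercises everything except ffprobe itself. Rational frame rates are
converted to decimal; when `r_frame_rate` and `avg_frame_rate` disagree
the file is flagged variable-framerate and the average rate is reported.
A consistency invariant `|n_frames − duration × fps| ≤ 1` absorbs
container rounding. Directory indexing probes every file matching a glob
pattern, sorted by filename; an empty match yields an empty index, not an
error.

## Synthetic clips and what they do (not) show

The generator emulates the estimator's *output*, not its vision problem:
each keypoint follows a motion program (static; linear drift in px/frame;
quadratic; or a raised-cosine burst), valid observations get optional
Gaussian position noise and confidences uniform in [0.6, 1.0], and chosen
(frame, point) cells are corrupted either to all-zero triplets or to
low-confidence observations with a large position error (40 px SD). All
randomness flows from one seed; regeneration is byte-identical. Ground
truth (noise-free positions and their velocity/acceleration/MF1, computed
by an explicitly naive per-point loop so it can serve as an independent
oracle) is returned with every clip.

Defaults mirror the typical stimulus recording the package targets: 125
frames at 25 fps (a 5 s clip), the `body25` model, pixel coordinates in a
640×480 frame. What passing tests show is that the bookkeeping,
imputation, and arithmetic are exact under controlled trajectories; what
they cannot show is robustness to real estimator behaviour — correlated
jitter, identity swaps between people, systematically misplaced but
confident fits — none of which the generator simulates.

Because no video decoder is a dependency, "video files" in tests and
examples are synthetic stand-ins: JSON stub files named like videos plus a
stub probe speaking the ffprobe contract (both clearly labelled
synthetic).

## Pipeline and reproducibility

The `run` pipeline chains convert → clean → velocity → acceleration →
Euclidean norms → plots, writing each stage under its conventional suffix
and recording every artifact (stage, parameters, input SHA-256) in
`manifest.json`. Parameters are validated before any stage runs. Batch
mode processes one subdirectory per clip, fail-fast by default with an
opt-in continue-on-error flag that records failures in the manifest.
Figures are rendered without timestamps so identical inputs produce
identical bytes.

## Numerical choices and problem sizes

Exactness is preferred over tolerance wherever the arithmetic allows:
static clips give exactly zero motion, fps doubling doubles values
exactly, and round trips are bit-exact. Where floating-point accumulation
enters (interpolation, norms of sums), tests assert agreement to 1e-9
absolute. Test and acceptance runs use desk-scale inputs — clips of 10–125
frames, 25 points, 100 random sequences for the oracle comparison — which
exercise every code path in seconds while keeping the closed-form expected
values hand-checkable.

## Known limitations

2-D pixel kinematics only: no camera calibration, no depth, no
normalization for actor distance or frame size, so MF1 values are
comparable only across clips with matching geometry. No smoothing is
applied, so high-frequency estimator jitter inflates velocity (and
especially acceleration) relative to the true body motion. Multi-person
tracking across frames, handshape analysis, and running the pose estimator
itself are out of scope.
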