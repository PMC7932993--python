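# posemotion

Quantify an actor's bodily motion in stimulus video clips from 2-D
body-pose keypoint tracking output.

Researchers in sign language and gesture studies present participants with
video clips of an actor signing or gesturing. Technical properties of such
stimuli (duration, frame rate, encoding) are easy to match across
experimental conditions; the *motion* the actor actually performs is not,
and systematic motion differences can confound condition contrasts — for
example by driving biological-motion-sensitive cortex differently across
conditions of a neuroimaging study. Pose-estimation systems such as
OpenPose fit a keypoint skeleton (25 body points, 70 face points, or 21
hand points) to every video frame, emitting one JSON file per frame with
an `(x, y, c)` triplet per keypoint — pixel position plus detection
confidence in [0, 1]. `posemotion` turns those per-frame files into
per-clip motion measures that can be used to match stimuli or as nuisance
regressors.

## The measure

For keypoint $i$ at frame transition $t \to t+1$, axis-wise velocity is the
frame-difference quotient

$$v_{t,i} = \frac{p_{t+1,i} - p_{t,i}}{\Delta t}, \qquad \Delta t = 1/\mathrm{fps},$$

in pixels/second (acceleration is the same quotient applied to velocity).
The scalar motion feature at each transition sums the $N$ per-point
velocity vectors **first** and then takes the Euclidean norm:

$$\mathrm{MF1}_t = \Bigl\lVert \sum_{i=1}^{N} v_{t,i} \Bigr\rVert ,$$

giving one non-negative value per frame transition — the clip's motion
time series — whose sum is the per-clip scalar used for condition
matching. Because vectors are summed before the norm, opposing movements
cancel; a sum-of-norms variant without cancellation is available as
`sum_of_norms`.

Before differencing, tracking dropouts are imputed: all-zero `(x, y, c)`
triplets (failed fits) and observations with confidence strictly below a
cutoff (default 0.3) are replaced by linear interpolation between the
nearest valid frames, so dropouts do not masquerade as motion.

## Worked example

```python
import posemotion as pm

# a synthetic 5 s clip: all 25 body points translate 1 px/frame at 25 fps
spec = pm.TrajectorySpec(n_frames=125, fps=25.0,
                         default_program=pm.MotionProgram("linear", dx=1.0))
seq, truth = pm.generate(spec, out_dir="frames/")   # writes 125 JSON files

agg = pm.aggregate_frames(sorted(__import__("pathlib").Path("frames").glob("*.json")),
                          "body25", fps=25.0)
cleaned, mask = pm.clean(agg, cutoff=0.3)
series = pm.motion_series(cleaned)                  # MF1 per transition
print(len(series.values), series.values[0])
print(pm.summarize_clip(series).total)
```

prints

```
124 625.0
77500.0
```

124 frame transitions; every one has MF1 = 625 px/s, the closed form
$N \cdot \mathrm{fps} \cdot \lVert d \rVert = 25 \times 25 \times 1$ for a
rigid translation of 1 px/frame; the per-clip total is $124 \times 625$.
The `examples/` directory holds one short script per capability
(conversion and cleaning, motion series and segment detection, arm
laterality, video metadata indexing, full pipeline with plots).

## Command line

Every capability is also a subcommand of the `posemotion` console script:

```
posemotion convert --input frames/ --model body25 --fps 25
posemotion clean   --input clip_body25.csv --cutoff 0.3
posemotion velocity --input clip_body25_cleaned.csv
posemotion en --vx clip_body25_cleaned_velocity_x.csv \
              --vy clip_body25_cleaned_velocity_y.csv
posemotion dethand --input clip_body25_cleaned.csv
posemotion run --input frames/ --output out/     # full chain + manifest
posemotion index --dir videos/ --pattern "*.mp4" --output index.csv
```

Output files follow the suffix conventions `_body25`, `_cleaned`,
`_velocity_x`/`_y`, `_en_velocity`, and so on; `run` writes a JSON
manifest listing every artifact with its stage, parameters, and input
hash, and re-runs on identical input are byte-identical.

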