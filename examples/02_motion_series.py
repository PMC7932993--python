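"""Compute velocity, acceleration, and the MF1 motion series for a clip.

The clip holds a single movement burst (frames 20-45) on the two wrist
keypoints; everything else stays still. MF1 at each frame transition is the
Euclidean norm of the sum of all 25 per-point velocity vectors, so the
burst appears as a peak and the still phases are exactly zero.
"""

import numpy as np

import posemotion as pm

spec = pm.TrajectorySpec(
    n_frames=75,
    fps=25.0,
    programs={
        4: pm.MotionProgram("burst", start=20, length=25, amplitude=60.0),
        7: pm.MotionProgram("burst", start=20, length=25, amplitude=60.0),
    },
    source_id="burst",
)
seq, truth = pm.generate(spec)

vel = pm.velocity(seq)
print(f"velocity field: {vel.vx.shape[0]} transitions x {vel.vx.shape[1]} points")

series = pm.euclidean_norm_of_sums(vel)
summary = pm.summarize_clip(series)
print(f"per-clip motion total: {summary.total:.1f} px/s")
print(f"peak {summary.peak:.1f} px/s at transition {summary.peak_transition} "
      f"(t = {series.times[summary.peak_transition]:.2f} s)")

segments = pm.detect_motion_segments(series, threshold_frac=0.1, min_len=3)
for onset, offset in segments:
    print(f"movement episode: transitions {onset}-{offset} "
          f"({series.times[onset]:.2f}-{series.times[offset]:.2f} s)")

quiet = np.concatenate([series.values[:19], series.values[46:]])
print(f"motion outside the burst window: max {quiet.max():.1f} px/s")
# The single detected episode brackets the programmed burst; the quiet
# phases contribute nothing because static points have zero velocity.
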