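"""Index a directory of video files by their technical metadata.

Metadata comes from an external probe binary (ffprobe by default). This
example has no decoder available, so it uses the package's synthetic
stand-ins: stub clip files plus a generated stub probe that answers in the
same JSON contract — the code path is identical to probing real video.
"""

import tempfile
from pathlib import Path

import posemotion as pm
from posemotion.synthetic import write_stub_clip, write_stub_probe

tmp = Path(tempfile.mkdtemp())
probe = write_stub_probe(tmp / "stub_probe")

for name, dur, fps in [("sign_a.mp4", 5.0, 25.0),
                       ("sign_b.mp4", 4.2, 25.0),
                       ("sign_c.mp4", 5.0, 50.0)]:
    write_stub_clip(tmp / name, duration_s=dur, fps=fps)

meta = pm.probe_video(tmp / "sign_a.mp4", probe_cmd=str(probe))
print(f"single probe: {meta.filename}: {meta.duration_s} s @ {meta.fps} fps, "
      f"{meta.n_frames} frames, {meta.width}x{meta.height} {meta.codec}")

index = pm.build_index(tmp, pattern="*.mp4",
                       output_csv=tmp / "index.csv", probe_cmd=str(probe))
print(index.to_string(index=False))
# A stimulus set matched on duration but not frame rate (sign_c) is easy to
# spot in the index; n_frames always equals duration x fps up to container
# rounding.
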