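"""Technical metadata of video files, via an external probe tool.

Stimulus sets should be matched not just on motion but on technical
properties (duration, frame rate, resolution, codec), so the package can
build a per-directory index of those properties. Decoding happens outside
the process: metadata is obtained by invoking a probe binary — ffprobe by
default — through a pinned subprocess contract (`PROBE_ARGS`): JSON output
with `format` and `streams` sections. Any executable honouring that
contract can be substituted via ``probe_cmd``, which is how the test suite
exercises the module without a real decoder.
"""

from __future__ import annotations

import json
import shutil
import subprocess
from dataclasses import dataclass, fields
from fnmatch import fnmatch
from pathlib import Path

import pandas as pd

__all__ = ["VideoMeta", "probe_video", "build_index", "ProbeError",
           "DEFAULT_PROBE", "PROBE_ARGS"]

DEFAULT_PROBE = "ffprobe"
# contract: <probe> *PROBE_ARGS <file> prints a JSON document with
# format.duration and one video stream carrying r_frame_rate (rational),
# avg_frame_rate, nb_frames, width, height, codec_name
PROBE_ARGS = (
    "-v", "error",
    "-print_format", "json",
    "-show_format",
    "-show_streams",
)


class ProbeError(RuntimeError):
    """The probe tool failed on, or could not interpret, a file."""


@dataclass
class VideoMeta:
    """Technical properties of one video file."""

    filename: str
    duration_s: float
    fps: float
    n_frames: int
    width: int
    height: int
    codec: str
    variable_framerate: bool = False

    def __post_init__(self) -> None:
        if min(self.duration_s, self.fps, self.width, self.height) <= 0:
            raise ValueError(
                f"{self.filename}: non-positive metadata field"
            )
        if abs(self.n_frames - self.duration_s * self.fps) > 1 + 1e-6:
            raise ValueError(
                f"{self.filename}: frame count {self.n_frames} inconsistent "
                f"with duration {self.duration_s} s at {self.fps} fps"
            )


def _rational(text: str) -> float:
    num, _, den = text.partition("/")
    den = den or "1"
    if float(den) == 0:
        return 0.0
    return float(num) / float(den)


def probe_video(path: str | Path, probe_cmd: str = DEFAULT_PROBE) -> VideoMeta:
    """Run the probe tool on one file and parse its JSON report."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if shutil.which(probe_cmd) is None:
        raise OSError(
            f"probe tool {probe_cmd!r} not found on PATH; install ffmpeg "
            "(which provides ffprobe) or pass probe_cmd="
        )
    proc = subprocess.run(
        [probe_cmd, *PROBE_ARGS, str(path)],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise ProbeError(
            f"{probe_cmd} failed on {path}: {proc.stderr.strip() or 'no diagnostic'}"
        )
    try:
        doc = json.loads(proc.stdout)
    except json.JSONDecodeError as exc:
        raise ProbeError(f"{probe_cmd} produced non-JSON output for {path}") from exc

    streams = [
        s for s in doc.get("streams", []) if s.get("codec_type") == "video"
    ]
    if not streams:
        raise ProbeError(f"{path}: no video stream found")
    stream = streams[0]
    fmt = doc.get("format", {})

    r_rate = _rational(str(stream.get("r_frame_rate", "0/1")))
    avg_rate = _rational(str(stream.get("avg_frame_rate", "0/1"))) or r_rate
    vfr = abs(avg_rate - r_rate) > 1e-9
    fps = avg_rate if vfr else r_rate

    duration = float(
        stream.get("duration") or fmt.get("duration") or 0.0
    )
    n_frames = int(
        stream.get("nb_frames") or round(duration * fps)
    )
    try:
        return VideoMeta(
            filename=path.name,
            duration_s=duration,
            fps=fps,
            n_frames=n_frames,
            width=int(stream.get("width", 0)),
            height=int(stream.get("height", 0)),
            codec=str(stream.get("codec_name", "unknown")),
            variable_framerate=vfr,
        )
    except ValueError as exc:
        raise ProbeError(str(exc)) from exc


def build_index(
    directory: str | Path,
    pattern: str = "*.mp4",
    output_csv: str | Path | None = None,
    probe_cmd: str = DEFAULT_PROBE,
) -> pd.DataFrame:
    """Probe every file in ``directory`` matching ``pattern``.

    Returns one row per file, sorted by filename; optionally also written
    as CSV. An empty match yields an empty (header-only) index, not an
    error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NotADirectoryError(directory)
    cols = [f.name for f in fields(VideoMeta)]
    rows = []
    for path in sorted(directory.iterdir()):
        if path.is_file() and fnmatch(path.name, pattern):
            meta = probe_video(path, probe_cmd=probe_cmd)
            rows.append({c: getattr(meta, c) for c in cols})
    index = pd.DataFrame(rows, columns=cols)
    if output_csv is not None:
        index.to_csv(output_csv, index=False)
    return index
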