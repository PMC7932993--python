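"""Synthetic keypoint clips with analytic ground truth.

Real inputs to this package come from a GPU pose-estimation run on video.
To make the whole pipeline testable without video, a GPU, or downloads,
this module generates per-frame JSON files in the same schema from a
declarative :class:`TrajectorySpec`: each keypoint follows a motion program
(static, linear drift, quadratic, or a smooth burst), optionally corrupted
with Gaussian position noise on valid cells and tracking dropout (all-zero
triplets or low-confidence cells) at chosen (frame, point) positions. The
noise-free trajectory is returned as ground truth together with its exact
velocity, acceleration, and MF1 series, computed by straightforward
per-point differencing — deliberately naive so it can double as an
independent oracle for the vectorized pipeline.

Also provided are *synthetic stand-ins* for video files: a stub clip is a
small JSON text file (named like a video) describing duration/fps/size, and
a stub probe is a generated executable that reports that description in the
video-probe subprocess contract. They exercise the metadata-indexing code
path; they are not decodable video.
"""

from __future__ import annotations

import json
import stat
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import serialize_frame
from .models import (
    LEFT_ARM_POINTS,
    RIGHT_ARM_POINTS,
    FramePose,
    KeypointModelSpec,
    PoseSequence,
    get_model,
)

__all__ = [
    "MotionProgram",
    "TrajectorySpec",
    "GroundTruth",
    "generate",
    "write_frame_files",
    "write_stub_clip",
    "write_stub_probe",
]

# valid cells get confidence in this range; dropout "lowconf" cells in [0, 0.3)
_VALID_CONF = (0.6, 1.0)
_LOWCONF_MAX = 0.3


@dataclass(frozen=True)
class MotionProgram:
    """How one keypoint moves, in pixels per frame units.

    kinds:
      - ``static``: stays at its base position
      - ``linear``: displaces by (dx, dy) every frame
      - ``quadratic``: position offset is (dx, dy) * t^2
      - ``burst``: smooth raised-cosine excursion of ``amplitude`` pixels
        (along +x) over frames [start, start+length)
    """

    kind: str = "static"
    dx: float = 0.0
    dy: float = 0.0
    start: int = 0
    length: int = 0
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "linear", "quadratic", "burst"):
            raise ValueError(f"unknown motion program kind {self.kind!r}")
        if self.kind == "burst" and self.length < 2:
            raise ValueError("burst programs need length >= 2")

    def offsets(self, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
        """Noise-free (x, y) displacement from base at every frame."""
        t = np.arange(n_frames, dtype=float)
        if self.kind == "static":
            return np.zeros(n_frames), np.zeros(n_frames)
        if self.kind == "linear":
            return self.dx * t, self.dy * t
        if self.kind == "quadratic":
            return self.dx * t**2, self.dy * t**2
        # burst: sin^2 window rises from 0 to amplitude and back
        dx = np.zeros(n_frames)
        inside = (t >= self.start) & (t < self.start + self.length)
        phase = (t[inside] - self.start) / self.length
        dx[inside] = self.amplitude * np.sin(np.pi * phase) ** 2
        return dx, np.zeros(n_frames)

    def is_moving(self) -> bool:
        if self.kind == "static":
            return False
        if self.kind == "burst":
            return self.amplitude != 0
        return self.dx != 0 or self.dy != 0


@dataclass
class TrajectorySpec:
    """Declarative description of a synthetic clip.

    ``programs`` maps point index -> :class:`MotionProgram`; unlisted points
    follow ``default_program``. ``dropout`` lists (frame, point) cells to
    corrupt, either as all-zero triplets (``dropout_mode="zero"``) or as
    low-confidence observations (``"lowconf"``).
    """

    n_frames: int = 125
    fps: float = 25.0
    model: str = "body25"
    default_program: MotionProgram = field(default_factory=MotionProgram)
    programs: dict[int, MotionProgram] = field(default_factory=dict)
    noise_sd: float = 0.0
    dropout: list[tuple[int, int]] = field(default_factory=list)
    dropout_mode: str = "zero"
    seed: int = 0
    source_id: str = "clip"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dropout_mode not in ("zero", "lowconf"):
            raise ValueError("dropout_mode must be 'zero' or 'lowconf'")
        spec = get_model(self.model)
        for frame, point in self.dropout:
            if not (0 <= frame < self.n_frames and 0 <= point < spec.n_points):
                raise ValueError(
                    f"dropout cell (frame={frame}, point={point}) outside "
                    f"the {self.n_frames}x{spec.n_points} clip"
                )
        for point in self.programs:
            if not 0 <= point < spec.n_points:
                raise ValueError(f"program for out-of-range point {point}")

    # -- JSON serialization (for the `fixtures` CLI subcommand) ------------

    def to_json(self) -> str:
        doc = asdict(self)
        doc["default_program"] = asdict(self.default_program)
        doc["programs"] = {str(k): asdict(v) for k, v in self.programs.items()}
        doc["dropout"] = [list(cell) for cell in self.dropout]
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrajectorySpec":
        doc = json.loads(text)
        doc["default_program"] = MotionProgram(**doc.get("default_program", {}))
        doc["programs"] = {
            int(k): MotionProgram(**v) for k, v in doc.get("programs", {}).items()
        }
        doc["dropout"] = [tuple(cell) for cell in doc.get("dropout", [])]
        return cls(**doc)


@dataclass
class GroundTruth:
    """Noise-free trajectory and its exact kinematics.

    All derivative arrays are computed by an explicit per-point loop over
    frame differences — an implementation intentionally independent of the
    package's vectorized kinematics.
    """

    x: np.ndarray  # (n_frames, n_points), noise-free
    y: np.ndarray
    vx: np.ndarray  # (n_frames-1, n_points), px/s
    vy: np.ndarray
    ax: np.ndarray  # (n_frames-2, n_points), px/s^2
    ay: np.ndarray
    mf1_velocity: np.ndarray  # (n_frames-1,)
    mf1_acceleration: np.ndarray  # (n_frames-2,)
    laterality: str  # left | right | both | none
    fps: float

    def as_sequence(self, model: str | KeypointModelSpec,
                    source_id: str = "truth") -> PoseSequence:
        """The uncorrupted trajectory as a sequence with unit confidence."""
        return PoseSequence(
            model, self.x, self.y, np.ones_like(self.x),
            fps=self.fps, source_id=source_id,
        )


def _base_positions(model: KeypointModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic resting layout: points on a grid inside a 640x480 frame."""
    n = model.n_points
    cols = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    x = 80.0 + 40.0 * (idx % cols)
    y = 60.0 + 40.0 * (idx // cols)
    return x, y


def _loop_kinematics(
    x: np.ndarray, y: np.ndarray, fps: float
) -> tuple[np.ndarray, ...]:
    """Naive per-point, per-frame reference kinematics (the oracle)."""
    n_frames, n_points = x.shape
    dt = 1.0 / fps
    vx = np.zeros((max(n_frames - 1, 0), n_points))
    vy = np.zeros_like(vx)
    for t in range(n_frames - 1):
        for i in range(n_points):
            vx[t, i] = (x[t + 1, i] - x[t, i]) / dt
            vy[t, i] = (y[t + 1, i] - y[t, i]) / dt
    ax = np.zeros((max(n_frames - 2, 0), n_points))
    ay = np.zeros_like(ax)
    for t in range(n_frames - 2):
        for i in range(n_points):
            ax[t, i] = (vx[t + 1, i] - vx[t, i]) / dt
            ay[t, i] = (vy[t + 1, i] - vy[t, i]) / dt

    def mf1(u: np.ndarray, w: np.ndarray) -> np.ndarray:
        out = np.zeros(u.shape[0])
        for t in range(u.shape[0]):
            sx = sum(u[t, i] for i in range(n_points))
            sy = sum(w[t, i] for i in range(n_points))
            out[t] = (sx**2 + sy**2) ** 0.5
        return out

    return vx, vy, ax, ay, mf1(vx, vy), mf1(ax, ay)


def _laterality_label(spec: TrajectorySpec, model: KeypointModelSpec) -> str:
    if model.name != "body25":
        return "none"

    def moving(points: tuple[int, ...]) -> bool:
        return any(
            spec.programs.get(p, spec.default_program).is_moving()
            for p in points
        )

    right, left = moving(RIGHT_ARM_POINTS), moving(LEFT_ARM_POINTS)
    if right and left:
        return "both"
    if right:
        return "right"
    if left:
        return "left"
    return "none"


def generate(
    spec: TrajectorySpec,
    out_dir: str | Path | None = None,
) -> tuple[PoseSequence, GroundTruth]:
    """Build a synthetic clip: observed (noisy, corrupted) sequence plus
    ground truth. When ``out_dir`` is given, also write one JSON frame
    file per frame (zero-padded numeric suffixes)."""
    model = get_model(spec.model)
    rng = np.random.default_rng(spec.seed)
    base_x, base_y = _base_positions(model)

    truth_x = np.empty((spec.n_frames, model.n_points))
    truth_y = np.empty_like(truth_x)
    for p in range(model.n_points):
        prog = spec.programs.get(p, spec.default_program)
        off_x, off_y = prog.offsets(spec.n_frames)
        truth_x[:, p] = base_x[p] + off_x
        truth_y[:, p] = base_y[p] + off_y

    vx, vy, ax, ay, mf1_v, mf1_a = _loop_kinematics(truth_x, truth_y, spec.fps)
    truth = GroundTruth(
        x=truth_x, y=truth_y, vx=vx, vy=vy, ax=ax, ay=ay,
        mf1_velocity=mf1_v, mf1_acceleration=mf1_a,
        laterality=_laterality_label(spec, model), fps=spec.fps,
    )

    obs_x = truth_x.copy()
    obs_y = truth_y.copy()
    if spec.noise_sd > 0:
        obs_x += rng.normal(0.0, spec.noise_sd, obs_x.shape)
        obs_y += rng.normal(0.0, spec.noise_sd, obs_y.shape)
    obs_c = rng.uniform(*_VALID_CONF, obs_x.shape)

    for frame, point in spec.dropout:
        if spec.dropout_mode == "zero":
            obs_x[frame, point] = 0.0
            obs_y[frame, point] = 0.0
            obs_c[frame, point] = 0.0
        else:
            obs_c[frame, point] = rng.uniform(0.0, _LOWCONF_MAX)
            # corrupt the position too: low confidence goes with a bad fit
            obs_x[frame, point] += rng.normal(0.0, 40.0)
            obs_y[frame, point] += rng.normal(0.0, 40.0)

    seq = PoseSequence(
        model, obs_x, obs_y, obs_c, fps=spec.fps, source_id=spec.source_id
    )
    if out_dir is not None:
        write_frame_files(seq, out_dir)
    return seq, truth


def write_frame_files(seq: PoseSequence, out_dir: str | Path) -> list[Path]:
    """Write one JSON document per frame, pose-estimator style."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in seq:
        path = out_dir / (
            f"{seq.source_id}_{frame.frame_index:012d}_keypoints.json"
        )
        path.write_text(serialize_frame(frame, seq.model), encoding="utf-8")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# synthetic video stand-ins

def write_stub_clip(
    path: str | Path,
    duration_s: float = 5.0,
    fps: float = 25.0,
    width: int = 640,
    height: int = 480,
    codec: str = "h264",
) -> Path:
    """Write a synthetic stand-in for a video file.

    The file is a small JSON description of the clip's technical metadata,
    readable only by the stub probe from :func:`write_stub_probe` — it is
    not decodable video.
    """
    path = Path(path)
    doc = {
        "synthetic_stub_video": True,
        "duration": duration_s,
        "fps": fps,
        "n_frames": int(round(duration_s * fps)),
        "width": width,
        "height": height,
        "codec": codec,
    }
    path.write_text(json.dumps(doc), encoding="utf-8")
    return path


_STUB_PROBE_SOURCE = '''#!{python}
"""Synthetic probe: speaks the video-probe subprocess contract for the
JSON stub clips written by posemotion.synthetic.write_stub_clip."""
import json, sys

path = sys.argv[-1]
try:
    with open(path) as fh:
        doc = json.load(fh)
    if not doc.get("synthetic_stub_video"):
        raise ValueError("not a stub clip")
except Exception as exc:
    sys.stderr.write(f"stub probe: cannot read {{path}}: {{exc}}\\n")
    sys.exit(1)

rate = f"{{int(round(doc['fps'] * 1000))}}/1000"
print(json.dumps({{
    "streams": [{{
        "codec_type": "video",
        "codec_name": doc["codec"],
        "width": doc["width"],
        "height": doc["height"],
        "r_frame_rate": rate,
        "avg_frame_rate": rate,
        "nb_frames": str(doc["n_frames"]),
        "duration": str(doc["duration"]),
    }}],
    "format": {{"duration": str(doc["duration"])}},
}}))
'''


def write_stub_probe(path: str | Path) -> Path:
    """Write an executable stub probe honouring the ffprobe JSON contract."""
    import sys

    path = Path(path)
    path.write_text(
        _STUB_PROBE_SOURCE.format(python=sys.executable), encoding="utf-8"
    )
    path.chmod(path.stat().st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
    return path
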