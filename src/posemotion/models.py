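"""Core data containers for 2-D body-pose keypoint sequences.

A pose-estimation system (OpenPose and compatible tools) fits a fixed
skeleton of named keypoints to every frame of a video and reports each
keypoint as an ``(x, y, confidence)`` triplet in image pixel coordinates
(origin top-left, y increasing downward). This module defines the model
catalogue (body25 / face / hand), the per-frame container, and the
per-clip container that the rest of the package operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "KeypointModelSpec",
    "FramePose",
    "PoseSequence",
    "BODY25",
    "FACE",
    "HAND_LEFT",
    "HAND_RIGHT",
    "MODELS",
    "get_model",
]

DEFAULT_FPS = 25.0

# body25 indices of the arm keypoints, used by laterality detection.
# "Right"/"left" are anatomical: the actor's right arm appears on the
# image's left side.
RIGHT_ARM_POINTS = (2, 3, 4)
LEFT_ARM_POINTS = (5, 6, 7)

_BODY25_LABELS = [
    "Nose", "Neck",
    "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist",
    "MidHip",
    "RHip", "RKnee", "RAnkle",
    "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar",
    "LBigToe", "LSmallToe", "LHeel",
    "RBigToe", "RSmallToe", "RHeel",
]

_HAND_LABELS = ["Wrist"] + [
    f"{finger}{joint}"
    for finger in ("Thumb", "Index", "Middle", "Ring", "Pinky")
    for joint in (1, 2, 3, 4)
]


@dataclass(frozen=True)
class KeypointModelSpec:
    """A named keypoint skeleton: which points exist and what they are called.

    The three standard models are exposed as module-level constants
    (:data:`BODY25`, :data:`FACE`, :data:`HAND_LEFT`/:data:`HAND_RIGHT`);
    ``json_key`` is the field under which the flat keypoint array appears
    in a per-frame JSON document.
    """

    name: str
    n_points: int
    labels: tuple
    json_key: str

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if len(self.labels) != self.n_points:
            raise ValueError(
                f"model {self.name!r}: {len(self.labels)} labels for "
                f"{self.n_points} points"
            )
        if len(set(self.labels)) != self.n_points:
            raise ValueError(f"model {self.name!r}: labels are not unique")


BODY25 = KeypointModelSpec(
    "body25", 25, tuple(_BODY25_LABELS), "pose_keypoints_2d"
)
FACE = KeypointModelSpec(
    "face", 70, tuple(f"Face{i}" for i in range(70)), "face_keypoints_2d"
)
HAND_LEFT = KeypointModelSpec(
    "hand_left", 21, tuple(_HAND_LABELS), "hand_left_keypoints_2d"
)
HAND_RIGHT = KeypointModelSpec(
    "hand_right", 21, tuple(_HAND_LABELS), "hand_right_keypoints_2d"
)

MODELS = {m.name: m for m in (BODY25, FACE, HAND_LEFT, HAND_RIGHT)}
# "hand" alone is ambiguous between the two sides; default to left, the
# side OpenPose writes first.
MODELS["hand"] = HAND_LEFT


def get_model(name: str | KeypointModelSpec) -> KeypointModelSpec:
    """Resolve a model name ("body25", "face", "hand_left", ...) to its spec."""
    if isinstance(name, KeypointModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown keypoint model {name!r}; known models: "
            f"{sorted(MODELS)}"
        ) from None


@dataclass
class FramePose:
    """Keypoint observations for one video frame.

    ``x``, ``y`` are pixel coordinates and ``c`` the detector's per-point
    confidence in [0, 1]; an all-zero triplet marks a failed fit.
    """

    frame_index: int
    x: np.ndarray
    y: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if not (self.x.shape == self.y.shape == self.c.shape):
            raise ValueError("x, y, c must have identical shapes")
        if self.x.ndim != 1:
            raise ValueError("x, y, c must be 1-D vectors")
        if np.any((self.c < 0) | (self.c > 1)):
            raise ValueError("confidence values must lie in [0, 1]")

    @property
    def n_points(self) -> int:
        return self.x.shape[0]

    def is_zero(self) -> bool:
        """True when every triplet is (0, 0, 0), i.e. no person was detected."""
        return not (np.any(self.x) or np.any(self.y) or np.any(self.c))


class PoseSequence:
    """A clip's worth of keypoint data: frames x points arrays of x, y, c.

    Parameters
    ----------
    model:
        The governing :class:`KeypointModelSpec` (or its name).
    x, y, c:
        Arrays of shape ``(n_frames, n_points)``.
    fps:
        Recording frame rate in frames per second (default 25).
    source_id:
        Identifier of the originating clip, used in output filenames.
    """

    def __init__(
        self,
        model: str | KeypointModelSpec,
        x: np.ndarray,
        y: np.ndarray,
        c: np.ndarray,
        fps: float = DEFAULT_FPS,
        source_id: str = "",
    ) -> None:
        self.model = get_model(model)
        self.x = np.atleast_2d(np.asarray(x, dtype=float))
        self.y = np.atleast_2d(np.asarray(y, dtype=float))
        self.c = np.atleast_2d(np.asarray(c, dtype=float))
        if not (self.x.shape == self.y.shape == self.c.shape):
            raise ValueError("x, y, c arrays must have identical shapes")
        if self.x.size and self.x.shape[1] != self.model.n_points:
            raise ValueError(
                f"{self.x.shape[1]} points per frame but model "
                f"{self.model.name!r} has {self.model.n_points}"
            )
        if not fps > 0:
            raise ValueError("fps must be positive")
        if self.c.size and np.any((self.c < 0) | (self.c > 1)):
            raise ValueError("confidence values must lie in [0, 1]")
        self.fps = float(fps)
        self.source_id = source_id

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[FramePose],
        model: str | KeypointModelSpec,
        fps: float = DEFAULT_FPS,
        source_id: str = "",
    ) -> "PoseSequence":
        """Stack per-frame poses; frame indices must be consecutive from 0."""
        model = get_model(model)
        indices = [f.frame_index for f in frames]
        if indices != list(range(len(frames))):
            raise ValueError(
                f"frame indices must be consecutive from 0, got {indices[:10]}..."
            )
        if frames:
            x = np.stack([f.x for f in frames])
            y = np.stack([f.y for f in frames])
            c = np.stack([f.c for f in frames])
        else:
            x = y = c = np.empty((0, model.n_points))
        return cls(model, x, y, c, fps=fps, source_id=source_id)

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_points(self) -> int:
        return self.model.n_points

    @property
    def duration(self) -> float:
        """Clip duration in seconds implied by frame count and fps."""
        return self.n_frames / self.fps

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[FramePose]:
        for t in range(self.n_frames):
            yield FramePose(t, self.x[t], self.y[t], self.c[t])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoseSequence):
            return NotImplemented
        return (
            self.model == other.model
            and self.fps == other.fps
            and self.x.shape == other.x.shape
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.c, other.c)
        )

    def copy(self) -> "PoseSequence":
        return PoseSequence(
            self.model,
            self.x.copy(),
            self.y.copy(),
            self.c.copy(),
            fps=self.fps,
            source_id=self.source_id,
        )

    def __repr__(self) -> str:
        return (
            f"PoseSequence(model={self.model.name!r}, n_frames={self.n_frames}, "
            f"fps={self.fps}, source_id={self.source_id!r})"
        )
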