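"""Per-point kinematics and the scalar motion time series.

Velocity is the frame-difference quotient ``(p_{t+1} - p_t) / Δt`` with
``Δt = 1/fps``, computed separately on the x and y axes for every keypoint;
acceleration is the same quotient applied to velocity. The clip-level
motion measure MF1 sums the N per-point velocity (or acceleration) vectors
at each frame transition *first* and then takes the Euclidean norm:

    MF1_t = || Σ_{i=1..N} v_{t,i} ||

so opposing movements cancel before the norm is taken. A sum-of-norms
variant (no cancellation) is available under a distinct name, never as the
default. One scalar per frame transition yields the motion time series; its
sum is the headline per-clip measure used for condition matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import PoseSequence

__all__ = [
    "VelocityField",
    "AccelField",
    "MotionSeries",
    "ClipSummary",
    "velocity",
    "acceleration",
    "euclidean_norm_of_sums",
    "sum_of_norms",
    "motion_series",
    "summarize_clip",
    "detect_motion_segments",
]


@dataclass
class VelocityField:
    """Axis-wise point velocities, pixels/second; row t is transition t→t+1."""

    vx: np.ndarray  # (n_frames-1, n_points)
    vy: np.ndarray
    fps: float
    quantity: str = field(default="velocity", init=False)
    # index of the first frame the first row refers to (velocity rows span
    # frames t..t+1 starting at t=0; used only for the time axis)
    start_frame: int = 1

    def __post_init__(self) -> None:
        if self.vx.shape != self.vy.shape:
            raise ValueError(
                f"axis arrays disagree: vx {self.vx.shape} vs vy {self.vy.shape}"
            )

    @property
    def n_transitions(self) -> int:
        return self.vx.shape[0]


@dataclass
class AccelField:
    """Axis-wise point accelerations, pixels/second^2."""

    ax: np.ndarray  # (n_frames-2, n_points)
    ay: np.ndarray
    fps: float
    quantity: str = field(default="acceleration", init=False)
    start_frame: int = 2

    def __post_init__(self) -> None:
        if self.ax.shape != self.ay.shape:
            raise ValueError(
                f"axis arrays disagree: ax {self.ax.shape} vs ay {self.ay.shape}"
            )

    @property
    def n_transitions(self) -> int:
        return self.ax.shape[0]


@dataclass
class MotionSeries:
    """One non-negative motion scalar per frame transition."""

    values: np.ndarray
    quantity: str  # "velocity" or "acceleration"
    fps: float
    start_frame: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a motion series is one-dimensional")

    @property
    def times(self) -> np.ndarray:
        """Time in seconds of each transition's later frame."""
        return (self.start_frame + np.arange(len(self.values))) / self.fps

    def __len__(self) -> int:
        return len(self.values)


def velocity(seq: PoseSequence) -> VelocityField:
    """First frame difference of positions, scaled to pixels/second."""
    if seq.n_frames < 2:
        raise ValueError(
            f"velocity needs at least 2 frames, sequence has {seq.n_frames}"
        )
    return VelocityField(
        vx=np.diff(seq.x, axis=0) * seq.fps,
        vy=np.diff(seq.y, axis=0) * seq.fps,
        fps=seq.fps,
    )


def acceleration(seq: PoseSequence) -> AccelField:
    """First frame difference of velocity, pixels/second^2."""
    if seq.n_frames < 3:
        raise ValueError(
            f"acceleration needs at least 3 frames, sequence has {seq.n_frames}"
        )
    v = velocity(seq)
    return AccelField(
        ax=np.diff(v.vx, axis=0) * seq.fps,
        ay=np.diff(v.vy, axis=0) * seq.fps,
        fps=seq.fps,
    )


def _axes(field: VelocityField | AccelField) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(field, VelocityField):
        return field.vx, field.vy
    if isinstance(field, AccelField):
        return field.ax, field.ay
    raise TypeError(f"expected a VelocityField or AccelField, got {type(field)}")


def euclidean_norm_of_sums(field: VelocityField | AccelField) -> MotionSeries:
    """MF1: sum the per-point vectors at each transition, then take the norm."""
    u, w = _axes(field)
    if u.shape != w.shape:
        raise ValueError("axis arrays disagree in shape")
    values = np.hypot(u.sum(axis=1), w.sum(axis=1))
    return MotionSeries(values, field.quantity, field.fps,
                        start_frame=field.start_frame)


def sum_of_norms(field: VelocityField | AccelField) -> MotionSeries:
    """Variant measure: per-point speeds summed, so motions never cancel.

    Not the package's headline measure; useful when opposing symmetric
    movements (e.g. both hands converging) should still register.
    """
    u, w = _axes(field)
    values = np.hypot(u, w).sum(axis=1)
    return MotionSeries(values, field.quantity, field.fps,
                        start_frame=field.start_frame)


def motion_series(seq: PoseSequence, quantity: str = "velocity") -> MotionSeries:
    """Clip → MF1 series in one step (velocity or acceleration)."""
    if quantity == "velocity":
        return euclidean_norm_of_sums(velocity(seq))
    if quantity == "acceleration":
        return euclidean_norm_of_sums(acceleration(seq))
    raise ValueError("quantity must be 'velocity' or 'acceleration'")


@dataclass
class ClipSummary:
    """Per-clip motion statistics; ``total`` is the condition-matching scalar."""

    total: float
    mean: float
    peak: float
    peak_transition: int


def summarize_clip(series: MotionSeries) -> ClipSummary:
    """Sum, mean, peak and argmax of a motion series."""
    if len(series) == 0:
        raise ValueError("cannot summarize an empty motion series")
    v = series.values
    return ClipSummary(
        total=float(v.sum()),
        mean=float(v.mean()),
        peak=float(v.max()),
        peak_transition=int(v.argmax()),
    )


def detect_motion_segments(
    series: MotionSeries,
    threshold_frac: float = 0.1,
    min_len: int = 3,
) -> list[tuple[int, int]]:
    """Find movement episodes: runs of transitions above a relative threshold.

    A transition is active when its value exceeds ``threshold_frac`` times
    the series maximum. Active runs closer than ``min_len`` transitions are
    merged, runs shorter than ``min_len`` dropped. Returns ``(onset,
    offset)`` pairs of transition indices, offset inclusive, in temporal
    order. A heuristic convenience for flagging candidate sign/gesture
    onsets and offsets — inspect the plotted series before trusting it.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if len(series) == 0:
        raise ValueError("cannot segment an empty motion series")
    v = series.values
    peak = v.max()
    if peak <= 0:
        return []
    active = v > threshold_frac * peak
    # run-length encode
    runs: list[list[int]] = []
    for t in np.flatnonzero(active):
        if runs and t == runs[-1][1] + 1:
            runs[-1][1] = t
        else:
            runs.append([t, t])
    # merge runs separated by short quiet gaps
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < min_len:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [
        (a, b) for a, b in merged if (b - a + 1) >= min_len
    ]
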