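"""Plots: frontal keypoint heatmap and motion time series.

Both plots are deterministic — fixed style, no timestamps — so identical
inputs produce identical figure files, which keeps rendered artifacts
diffable across pipeline re-runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .cleaning import DEFAULT_CUTOFF, find_invalid
from .kinematics import MotionSeries
from .models import PoseSequence

__all__ = ["HeatmapSpec", "frontal_histogram", "plot_frontal", "plot_timeseries"]


@dataclass
class HeatmapSpec:
    """Binning parameters for the frontal heatmap.

    ``extent`` is the (width, height) of the image in pixels; when None it
    is taken from the data's bounding box. ``invert_y`` flips the vertical
    axis so the rendered figure matches screen orientation (keypoint
    coordinates have y increasing downward).
    """

    bin_size: float = 10.0
    extent: tuple[float, float] | None = None
    invert_y: bool = True

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.extent is not None and min(self.extent) <= 0:
            raise ValueError("extent must be positive")


def frontal_histogram(
    seq: PoseSequence,
    spec: HeatmapSpec | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of all valid (x, y) observations across frames.

    Returns ``(counts, x_edges, y_edges)``; counts sum to the number of
    valid (frame, point) cells.
    """
    spec = spec or HeatmapSpec()
    valid = find_invalid(seq, cutoff).valid
    xs = seq.x[valid]
    ys = seq.y[valid]
    if spec.extent is not None:
        width, height = spec.extent
        x_range, y_range = (0.0, width), (0.0, height)
    elif xs.size:
        x_range = (xs.min(), max(xs.max(), xs.min() + spec.bin_size))
        y_range = (ys.min(), max(ys.max(), ys.min() + spec.bin_size))
    else:
        x_range, y_range = (0.0, spec.bin_size), (0.0, spec.bin_size)
    x_edges = np.arange(x_range[0], x_range[1] + spec.bin_size, spec.bin_size)
    y_edges = np.arange(y_range[0], y_range[1] + spec.bin_size, spec.bin_size)
    counts, xe, ye = np.histogram2d(xs, ys, bins=[x_edges, y_edges])
    return counts, xe, ye


def plot_frontal(
    seq: PoseSequence,
    spec: HeatmapSpec | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    out: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Heatmap of where keypoints were observed over the whole clip."""
    spec = spec or HeatmapSpec()
    counts, xe, ye = frontal_histogram(seq, spec, cutoff)
    if counts.sum() == 0:
        warnings.warn(
            f"clip {seq.source_id!r}: no valid observations, heatmap is empty",
            stacklevel=2,
        )
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    mesh = ax.pcolormesh(xe, ye, counts.T, cmap="viridis", shading="flat")
    fig.colorbar(mesh, ax=ax, label="observations per bin")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(seq.source_id or "keypoint density")
    ax.set_aspect("equal")
    if spec.invert_y:
        ax.invert_yaxis()
    if out is not None:
        fig.savefig(out, metadata=_no_timestamp(Path(out)))
        plt.close(fig)
    return fig


def plot_timeseries(
    series: MotionSeries,
    segments: list[tuple[int, int]] | None = None,
    out: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Line plot of the motion series against time in seconds.

    ``segments`` (transition-index pairs, e.g. from
    :func:`~posemotion.kinematics.detect_motion_segments`) are shaded to
    mark movement episodes such as a sign's onset and offset.
    """
    if len(series) == 0:
        raise ValueError("cannot plot an empty motion series")
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 3.2))
    else:
        fig = ax.figure
    unit = "px/s" if series.quantity == "velocity" else "px/s$^2$"
    ax.plot(series.times, series.values, color="#1f4e79", lw=1.2)
    for onset, offset in segments or []:
        ax.axvspan(
            series.times[onset], series.times[offset],
            color="#e8a33d", alpha=0.3, lw=0,
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{series.quantity} ({unit})")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, metadata=_no_timestamp(Path(out)))
        plt.close(fig)
    return fig


def _no_timestamp(path: Path) -> dict:
    """Metadata overrides that strip per-run timestamps from figure files."""
    if path.suffix.lower() == ".svg":
        return {"Date": None}
    if path.suffix.lower() in (".pdf", ".ps", ".eps"):
        return {"CreationDate": None}
    return {}
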