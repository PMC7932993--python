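"""Detection and imputation of failed keypoint observations.

Tracking output contains two kinds of bad cells: all-zero ``(x, y, c)``
triplets, written when the model fit failed outright for a point, and
observations whose confidence falls below a cutoff (default 0.3). Left in
place, either makes points appear to jump between frames and corrupts the
velocity and acceleration estimates, so both are replaced before
differencing: an isolated bad frame gets the mean of its valid neighbours,
a run of bad frames is linearly interpolated between the bounding valid
frames, and runs touching a clip boundary take the nearest valid value.
Confidence values are never rewritten — the validity mask is returned
alongside as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import PoseSequence
from . import io as _io

__all__ = ["ValidityMask", "find_invalid", "impute", "clean", "clean_file",
           "DEFAULT_CUTOFF", "UnimputablePointError"]

DEFAULT_CUTOFF = 0.3


class UnimputablePointError(ValueError):
    """A keypoint has no valid observation anywhere in the clip."""


@dataclass
class ValidityMask:
    """Per-frame, per-point validity flags (True = observation usable)."""

    valid: np.ndarray  # bool, (n_frames, n_points)
    cutoff: float

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in [0, 1], got {self.cutoff}")


def find_invalid(seq: PoseSequence, cutoff: float = DEFAULT_CUTOFF) -> ValidityMask:
    """Flag all-zero triplets and observations with confidence strictly
    below ``cutoff``."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    zero = (seq.x == 0) & (seq.y == 0) & (seq.c == 0)
    low = seq.c < cutoff
    return ValidityMask(valid=~(zero | low), cutoff=cutoff)


def impute(
    seq: PoseSequence, mask: ValidityMask
) -> tuple[PoseSequence, ValidityMask]:
    """Replace invalid x/y cells by interpolation from valid frames.

    Returns the cleaned sequence together with the mask actually applied,
    so callers can tell imputed cells apart later (confidences are left
    untouched and may still sit below the cutoff).
    """
    if mask.valid.shape != seq.x.shape:
        raise ValueError(
            f"mask shape {mask.valid.shape} does not match sequence "
            f"{seq.x.shape}"
        )
    out = seq.copy()
    frames = np.arange(seq.n_frames, dtype=float)
    for p in range(seq.n_points):
        good = mask.valid[:, p]
        if good.all():
            continue
        if not good.any():
            raise UnimputablePointError(
                f"point {p} ({seq.model.labels[p]}) has no valid observation "
                "in the clip"
            )
        bad = ~good
        # np.interp clamps outside the valid range, which implements the
        # nearest-valid fill for runs touching a clip boundary.
        out.x[bad, p] = np.interp(frames[bad], frames[good], seq.x[good, p])
        out.y[bad, p] = np.interp(frames[bad], frames[good], seq.y[good, p])
    return out, mask


def clean(
    seq: PoseSequence, cutoff: float = DEFAULT_CUTOFF
) -> tuple[PoseSequence, ValidityMask]:
    """Convenience: :func:`find_invalid` followed by :func:`impute`."""
    return impute(seq, find_invalid(seq, cutoff))


def clean_file(
    path: str | Path,
    cutoff: float = DEFAULT_CUTOFF,
    overwrite: bool = False,
) -> Path:
    """Clean a CSV table on disk.

    Writes ``<stem>_cleaned.csv`` next to the input (or replaces the input
    when ``overwrite=True``) and returns the output path. The cutoff is
    validated before anything is read or written.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    path = Path(path)
    seq = _io.read_table(path)
    cleaned, _ = clean(seq, cutoff)
    out = path if overwrite else path.with_name(path.stem + "_cleaned.csv")
    _io.write_table(cleaned, out)
    return out
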