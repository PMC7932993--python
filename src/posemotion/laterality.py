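"""Classify which arm(s) the actor moved (the ``det_hand`` analogue).

Works on the body25 model only. Each side's motion is the summed speed
(sqrt(vx^2 + vy^2), over all transitions) of its three arm keypoints —
shoulder, elbow, wrist: right = indices 2, 3, 4; left = 5, 6, 7. Labels are
anatomical: the actor's right arm appears on the image's left. The decision
rule, its keypoint subset, and both thresholds are this package's own
design; they are configurable and documented rather than taken from any
published reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import velocity
from .models import LEFT_ARM_POINTS, RIGHT_ARM_POINTS, PoseSequence

__all__ = ["LateralityResult", "det_hand",
           "DEFAULT_REL_THRESHOLD", "DEFAULT_NONE_FLOOR"]

DEFAULT_REL_THRESHOLD = 0.5
# summed speed (px/s over the whole clip) below which a side counts as still
DEFAULT_NONE_FLOOR = 1.0


@dataclass
class LateralityResult:
    """Outcome of arm-laterality detection for one clip.

    ``ratio`` is min(side)/max(side) in [0, 1]; 1.0 when both sides are
    exactly zero (trivially balanced, labelled "none" via the floor).
    """

    label: str  # left | right | both | none
    left_motion: float
    right_motion: float
    ratio: float


def det_hand(
    seq: PoseSequence,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    none_floor: float = DEFAULT_NONE_FLOOR,
) -> LateralityResult:
    """Determine whether the left, right, both, or neither arm moved.

    "none" when both sides' summed speeds fall below ``none_floor``;
    "both" when the quieter side reaches ``rel_threshold`` of the busier
    one; otherwise the busier side's label.
    """
    if seq.model.name != "body25":
        raise ValueError(
            f"laterality detection requires the body25 model, got "
            f"{seq.model.name!r}"
        )
    if not 0.0 < rel_threshold <= 1.0:
        raise ValueError(f"rel_threshold must be in (0, 1], got {rel_threshold}")
    v = velocity(seq)
    speed = np.hypot(v.vx, v.vy)  # (n_transitions, n_points)
    right = float(speed[:, list(RIGHT_ARM_POINTS)].sum())
    left = float(speed[:, list(LEFT_ARM_POINTS)].sum())

    lo, hi = min(left, right), max(left, right)
    ratio = lo / hi if hi > 0 else 1.0
    if hi < none_floor:
        label = "none"
    elif ratio >= rel_threshold:
        label = "both"
    elif left > right:
        label = "left"
    else:
        label = "right"
    return LateralityResult(
        label=label, left_motion=left, right_motion=right, ratio=ratio
    )
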