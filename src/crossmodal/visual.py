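"""Visual periphery: geometric directional cue from a Kinect-like field of view.

The visual receptive field is a head-centred wedge 57 degrees wide and 4 m
deep.  Inside it, the target's bearing maps one-to-one onto a directional
cue in [-1, +1] (field boundaries map to +/-1, the centre to 0); outside
it, the cue is *exactly* zero, modelling a target that is simply not
detected.  Noise is injected downstream, and only while the target is
visible, so the inside-centre cue is noisy-nonzero while the outside cue
stays exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .agent import Pose, bearing_to, target_range
from .world import TargetState

__all__ = ["VisualCue", "VisualField", "visual_cue"]


@dataclass(frozen=True)
class VisualField:
    """Angular width (degrees) and range limit (metres) of the field."""

    width_deg: float = 57.0
    depth_m: float = 4.0

    @property
    def half_width_rad(self) -> float:
        return math.radians(self.width_deg) / 2.0


@dataclass(frozen=True)
class VisualCue:
    """Directional cue in [-1, +1]; exactly 0 when the target is unseen."""

    x_v: float
    visible: bool


def visual_cue(
    target: TargetState, pose: Pose, field: VisualField = VisualField()
) -> VisualCue:
    """Geometric visual cue: ``bearing / (width/2)`` inside the field, else 0."""
    bearing = bearing_to(pose, target.position)
    half = field.half_width_rad
    # boundaries are part of the field (they map to the cue extremes +/-1);
    # the epsilon absorbs rounding in the bearing computation
    if (
        abs(bearing) <= half + 1e-9
        and target_range(pose, target.position) <= field.depth_m
    ):
        return VisualCue(x_v=min(1.0, max(-1.0, bearing / half)), visible=True)
    return VisualCue(x_v=0.0, visible=False)
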