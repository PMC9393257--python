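"""Differential-drive agent: pose, forward kinematics, and the reflexive turn controller.

The agent is a two-wheeled non-holonomic robot with wheel separation ``l``
(16 cm by default).  In the tracking task it only ever rotates on the spot:
the fused motor output ``v`` from the multisensory neuron is assigned to both
wheels with equal magnitude and opposite sign, so the agent turns toward the
side the fused cue points at.  Translation is nevertheless implemented in the
kinematics, which use the standard instantaneous-centre-of-curvature (ICC)
update with angular velocity ``omega = (v_r - v_l) / l`` and ICC distance
``D = (l / 2) * (v_r + v_l) / (v_r - v_l)``.

Conventions
-----------
* ``theta`` is the heading in radians, wrapped to ``(-pi, pi]``; the heading
  unit vector is ``(cos(theta), sin(theta))``.
* Bearings are measured clockwise from the heading: a *positive* bearing
  means the target is to the agent's *right*.
* A positive fused output therefore commands a clockwise (rightward)
  rotation, closing a negative-feedback loop around the bearing error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WHEEL_SEPARATION_M",
    "Pose",
    "WheelCommand",
    "bearing_to",
    "command_from_speed",
    "forward_kinematics",
    "wrap_angle",
]

#: Linear separation between the two wheels, in metres.
WHEEL_SEPARATION_M = 0.16


def wrap_angle(angle: float) -> float:
    """Wrap an angle in radians to the interval ``(-pi, pi]``."""
    wrapped = math.remainder(angle, 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class Pose:
    """Agent pose ``[x, y, theta]`` in the planar arena (metres, radians)."""

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", wrap_angle(self.theta))


@dataclass(frozen=True)
class WheelCommand:
    """Signed wheel speeds (m per time unit) plus the wheel separation."""

    v_l: float
    v_r: float
    l: float = WHEEL_SEPARATION_M

    @property
    def omega(self) -> float:
        """Angular velocity ``(v_r - v_l) / l``."""
        return (self.v_r - self.v_l) / self.l

    @property
    def icc_distance(self) -> float:
        """Distance ``D`` to the instantaneous centre of curvature.

        Infinite for straight-line motion (``v_l == v_r``).
        """
        if self.v_r == self.v_l:
            return math.inf
        return (self.l / 2.0) * (self.v_r + self.v_l) / (self.v_r - self.v_l)


def bearing_to(pose: Pose, point) -> float:
    """Signed head-centred bearing of ``point``, positive to the agent's right.

    Returns a value in ``(-pi, pi]``; magnitudes above ``pi/2`` mean the
    point lies behind the frontal semicircle.
    """
    phi = math.atan2(point[1] - pose.y, point[0] - pose.x)
    return wrap_angle(pose.theta - phi)


def target_range(pose: Pose, point) -> float:
    """Euclidean distance from the agent to ``point``."""
    return math.hypot(point[0] - pose.x, point[1] - pose.y)


def command_from_speed(v: float, l: float = WHEEL_SEPARATION_M) -> WheelCommand:
    """Turn the fused motor output into an on-the-spot rotation command.

    Both wheels get magnitude ``|v|`` with opposite signs.  For ``v > 0``
    (target to the right) the command is ``(v_l, v_r) = (+v, -v)``, giving
    ``omega < 0``: a clockwise rotation that reduces a positive bearing.
    """
    return WheelCommand(v_l=v, v_r=-v, l=l)


def forward_kinematics(pose: Pose, cmd: WheelCommand, dt: float) -> Pose:
    """Advance the pose by one kinematic step of duration ``dt``.

    Straight-line motion (``v_l == v_r``) is handled as the translation
    limit; otherwise the pose is rotated about the ICC by ``omega * dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cmd.v_l == cmd.v_r:
        dist = cmd.v_l * dt
        return Pose(
            x=pose.x + dist * math.cos(pose.theta),
            y=pose.y + dist * math.sin(pose.theta),
            theta=pose.theta,
        )
    omega = cmd.omega
    d = cmd.icc_distance
    icc_x = pose.x - d * math.sin(pose.theta)
    icc_y = pose.y + d * math.cos(pose.theta)
    dtheta = omega * dt
    cos_a, sin_a = math.cos(dtheta), math.sin(dtheta)
    rel_x, rel_y = pose.x - icc_x, pose.y - icc_y
    return Pose(
        x=icc_x + cos_a * rel_x - sin_a * rel_y,
        y=icc_y + sin_a * rel_x + cos_a * rel_y,
        theta=pose.theta + dtheta,
    )
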