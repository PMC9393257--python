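"""Synthetic audio-visual world: target motion, sound duty cycle, binaural signal.

The target performs a random zig-zag crossing from the agent's right to its
left.  Its along-track speed is redrawn uniformly from [0, 10] (arbitrary
units per time step) every 5-10 steps, and its cross-track speed from [0, 4]
(with a random sign per segment) every 0-5 steps.  Sound emission follows a
random duty cycle: off for 5-10 steps, then on for 10-15 steps, repeating.

While emitting, the target is heard as a pair of equal-amplitude sinusoids
(2.2 kHz by default) whose interaural phase offset encodes the bearing:

    dphi = 2 * pi * f * d * sin(theta) / c

with sensor separation ``d`` = 13 mm and speed of sound ``c`` = 340 m/s.
Interaural level differences, distance attenuation, and reverberation are
all absent by construction; only the frontal azimuth semicircle is modelled,
and bearings beyond +/-90 degrees are clamped (with a log warning).

Because the nominal speed units are large relative to the 4 m-deep visual
field, displacements are applied through a configurable ``speed_scale``
(default 1 in :func:`step_target`; the trial runner passes the world's
scale) so that one trial corresponds to roughly one crossing within sensor
range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .agent import Pose, bearing_to

__all__ = [
    "AcousticParams",
    "BinauralSignal",
    "SoundSchedule",
    "TargetState",
    "TrajectorySchedule",
    "emit_binaural",
    "equivalent_peak_frequency",
    "generate_trajectory",
    "phase_difference",
    "sound_duty_schedule",
    "step_target",
    "wavelength",
]

logger = logging.getLogger(__name__)

ALONG_SPEED_RANGE = (0.0, 10.0)
ALONG_HOLD_RANGE = (5, 10)
CROSS_SPEED_RANGE = (0.0, 4.0)
CROSS_HOLD_RANGE = (0, 5)
OFF_RANGE = (5, 10)
ON_RANGE = (10, 15)


def phase_difference(f: float, d: float, theta: float, c: float = 340.0) -> float:
    """Interaural phase difference ``2*pi*f*d*sin(theta)/c`` in radians.

    ``theta`` is the bearing in radians (positive right); ``f`` in Hz,
    ``d`` in metres, ``c`` in m/s.
    """
    return 2.0 * math.pi * f * d * math.sin(theta) / c


def equivalent_peak_frequency(d: float, f_ref: float = 1500.0, d_ref: float = 0.013) -> float:
    """Tone frequency giving the same peak phase difference at separation ``d``.

    The peak phase difference scales with the product ``f * d``, so the
    equivalent frequency for a new separation is ``f_ref * d_ref / d``.
    """
    if d <= 0:
        raise ValueError("sensor separation must be positive")
    return f_ref * d_ref / d


def wavelength(f: float, c: float = 340.0) -> float:
    """Acoustic wavelength ``c / f`` in metres."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return c / f


@dataclass(frozen=True)
class AcousticParams:
    """Parameters of the emitted tone and of the binaural sampling window."""

    f: float = 2200.0  # tone frequency, Hz
    d: float = 0.013  # sensor separation, m
    c: float = 340.0  # speed of sound, m/s
    amplitude: float = 1.0  # peak amplitude, arbitrary units
    sample_rate: float = 44100.0  # samples/s
    window: int = 512  # samples per simulation time step

    def __post_init__(self) -> None:
        if self.window * self.f < 2.0 * self.sample_rate:
            raise ValueError("window must span at least two cycles of the tone")

    @property
    def max_phase_difference(self) -> float:
        """Largest attainable |dphi|, at a bearing of +/-90 degrees."""
        return 2.0 * math.pi * self.f * self.d / self.c


@dataclass(frozen=True)
class BinauralSignal:
    """One window of left/right samples; all-zero while the sound is off."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right channels must have equal length")

    @property
    def is_silent(self) -> bool:
        return not (np.any(self.left) or np.any(self.right))


@dataclass
class TrajectorySchedule:
    """Piecewise-constant along/cross-track speed segments for one crossing.

    ``along`` and ``cross`` are lists of ``(speed, hold)`` pairs with speeds
    in the nominal unit ranges [0, 10] and [0, 4] and integer hold durations
    in {5..10} and {0..5}.  ``cross_signs`` carries an independent random
    sign per cross segment (the zig in the zig-zag).  ``direction`` is the
    unit vector of net motion: right-to-left, i.e. (-1, 0).
    """

    along: list[tuple[float, int]]
    cross: list[tuple[float, int]]
    cross_signs: list[int]
    direction: tuple[float, float] = (-1.0, 0.0)
    _along_per_step: np.ndarray = field(default=None, repr=False, compare=False)
    _cross_per_step: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._along_per_step = np.repeat(
            [s for s, _ in self.along], [h for _, h in self.along]
        )
        signed = [s * g for (s, _), g in zip(self.cross, self.cross_signs)]
        self._cross_per_step = np.repeat(signed, [h for _, h in self.cross])

    @property
    def n_steps(self) -> int:
        return min(len(self._along_per_step), len(self._cross_per_step))

    def speeds_at(self, t: int) -> tuple[float, float]:
        """(along-track speed, signed cross-track speed) at step ``t``."""
        if not 0 <= t < self.n_steps:
            raise IndexError(f"step {t} outside schedule coverage ({self.n_steps})")
        return float(self._along_per_step[t]), float(self._cross_per_step[t])


@dataclass
class SoundSchedule:
    """Alternating (off, on) interval pairs, in time steps, starting off."""

    intervals: list[tuple[int, int]]
    _on_per_step: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        flags: list[np.ndarray] = []
        for off, on in self.intervals:
            flags.append(np.zeros(off, dtype=bool))
            flags.append(np.ones(on, dtype=bool))
        self._on_per_step = np.concatenate(flags) if flags else np.zeros(0, dtype=bool)

    @property
    def n_steps(self) -> int:
        return len(self._on_per_step)

    def sound_on(self, t: int) -> bool:
        if not 0 <= t < self.n_steps:
            raise IndexError(f"step {t} outside sound schedule ({self.n_steps})")
        return bool(self._on_per_step[t])


@dataclass(frozen=True)
class TargetState:
    """Target position (m), emission flag, and time-step index."""

    position: tuple[float, float]
    sound_on: bool
    t: int

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("time-step index must be non-negative")
        if not all(math.isfinite(p) for p in self.position):
            raise ValueError("target position must be finite")


def generate_trajectory(n_steps: int, rng: np.random.Generator) -> TrajectorySchedule:
    """Draw a random zig-zag speed schedule covering at least ``n_steps``."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    along: list[tuple[float, int]] = []
    covered = 0
    while covered < n_steps:
        speed = float(rng.uniform(*ALONG_SPEED_RANGE))
        hold = int(rng.integers(ALONG_HOLD_RANGE[0], ALONG_HOLD_RANGE[1] + 1))
        along.append((speed, hold))
        covered += hold
    cross: list[tuple[float, int]] = []
    signs: list[int] = []
    covered = 0
    while covered < n_steps:
        speed = float(rng.uniform(*CROSS_SPEED_RANGE))
        hold = int(rng.integers(CROSS_HOLD_RANGE[0], CROSS_HOLD_RANGE[1] + 1))
        cross.append((speed, hold))
        signs.append(1 if rng.random() < 0.5 else -1)
        covered += hold
    return TrajectorySchedule(along=along, cross=cross, cross_signs=signs)


def sound_duty_schedule(n_steps: int, rng: np.random.Generator) -> SoundSchedule:
    """Draw the random emission duty cycle covering at least ``n_steps``."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    intervals: list[tuple[int, int]] = []
    covered = 0
    while covered < n_steps:
        off = int(rng.integers(OFF_RANGE[0], OFF_RANGE[1] + 1))
        on = int(rng.integers(ON_RANGE[0], ON_RANGE[1] + 1))
        intervals.append((off, on))
        covered += off + on
    return SoundSchedule(intervals=intervals)


def step_target(
    state: TargetState,
    schedule: TrajectorySchedule,
    sound: SoundSchedule,
    speed_scale: float = 1.0,
) -> TargetState:
    """Advance the target by one time step along its schedule.

    Displacement is ``speed_scale`` times the scheduled along/cross-track
    speeds; the emission flag is looked up from the duty cycle at ``t + 1``.
    """
    v_along, v_cross = schedule.speeds_at(state.t)
    dx, dy = schedule.direction
    # perpendicular (90 deg counter-clockwise) to the direction of motion
    px, py = -dy, dx
    x = state.position[0] + speed_scale * (v_along * dx + v_cross * px)
    y = state.position[1] + speed_scale * (v_along * dy + v_cross * py)
    return TargetState(position=(x, y), sound_on=sound.sound_on(state.t + 1), t=state.t + 1)


def schedule_frame(
    schedule: TrajectorySchedule,
    sound: SoundSchedule,
    start: tuple[float, float],
    n_steps: int,
    speed_scale: float = 1.0,
):
    """Tabulate a target path as a DataFrame with columns t, x, y, sound_on.

    Rolls the schedules forward from ``start`` for ``n_steps`` steps;
    suitable for CSV export of a generated crossing.
    """
    import pandas as pd

    state = TargetState(position=start, sound_on=sound.sound_on(0), t=0)
    rows = []
    for _ in range(n_steps):
        rows.append(
            {"t": state.t, "x": state.position[0], "y": state.position[1],
             "sound_on": state.sound_on}
        )
        state = step_target(state, schedule, sound, speed_scale)
    return pd.DataFrame(rows)


def emit_binaural(
    state: TargetState, pose: Pose, params: AcousticParams = AcousticParams()
) -> BinauralSignal:
    """One window of the binaural tone pair perceived at the agent's sensors.

    The right channel leads by ``+dphi/2`` and the left lags by ``-dphi/2``
    when the target is to the agent's right.  Returns silence while the
    emission is off.  Bearings outside the frontal semicircle are clamped to
    +/-90 degrees (logged), as only lateral localization is modelled.
    """
    n = params.window
    if not state.sound_on:
        zero = np.zeros(n)
        return BinauralSignal(left=zero, right=zero.copy(), sample_rate=params.sample_rate)
    theta = bearing_to(pose, state.position)
    if abs(theta) > math.pi / 2.0:
        logger.warning(
            "bearing %.1f deg outside the frontal semicircle; clamping to +/-90",
            math.degrees(theta),
        )
        theta = math.copysign(math.pi / 2.0, theta)
    dphi = phase_difference(params.f, params.d, theta, params.c)
    t = np.arange(n) / params.sample_rate
    omega = 2.0 * math.pi * params.f
    left = params.amplitude * np.sin(omega * t - dphi / 2.0)
    right = params.amplitude * np.sin(omega * t + dphi / 2.0)
    return BinauralSignal(left=left, right=right, sample_rate=params.sample_rate)
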