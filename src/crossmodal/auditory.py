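"""Auditory periphery: band-pass eardrum filter pair and the directional cue.

The periphery mimics a pressure-difference receiver of the kind found in
lizard ears: each eardrum is driven by the ipsilateral sound directly and by
the contralateral sound through an internal path with attenuation and a
short delay.  Both paths share a mirrored 4th-order digital band-pass
(1-4 kHz); the contralateral branch additionally applies a negative gain
and a 4-sample delay at 44.1 kHz.  For a tone of frequency ``f`` arriving
with interaural phase ``dphi`` the steady-state output powers are, in
phasor form, ``1 + g**2 + 2*g*cos(2*pi*f*n_delay/fs +/- dphi)``, so the dB
power difference is an odd, monotone function of bearing whose frequency
response (gain -0.6, delay 4 samples) peaks near 2.2 kHz and falls off
toward the band edges.

The directional cue is the left/right output power difference in dB,
normalised by a calibration constant (the maximal noiseless difference over
the frontal semicircle at the nominal tone frequency) and clipped to
[-1, +1].  A closed-form surrogate backend (``x_a = sin(bearing)``) is
available for backend-agnostic downstream use.

No noise filtering is performed: noise injected into the raw signals passes
through to the cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .agent import Pose
from .world import AcousticParams, BinauralSignal, TargetState, emit_binaural

__all__ = [
    "AuditoryCue",
    "EardrumFilterSpec",
    "auditory_cue",
    "calibrate",
    "eardrum_filter",
    "surrogate_cue",
]

#: Shortest window the 4th-order band-pass is allowed to see (settling).
MIN_WINDOW = 128


@dataclass(frozen=True)
class EardrumFilterSpec:
    """Mirrored two-input/two-output eardrum filter pair.

    ``band`` is the pass band in Hz of the shared 4th-order band-pass
    (Butterworth, order-2 prototype -> 4th-order polynomial).
    ``contra_gain`` and ``contra_delay`` (samples) define the internal
    contralateral path; together they place the peak of the binaural
    difference response near 2.2 kHz (gain -0.6, 4 samples at 44.1 kHz).
    """

    band: tuple[float, float] = (1000.0, 4000.0)
    order: int = 2
    contra_gain: float = -0.6
    contra_delay: int = 4
    sample_rate: float = 44100.0


@dataclass(frozen=True)
class AuditoryCue:
    """Directional cue in [-1, +1]; exactly 0 when nothing is audible."""

    x_a: float
    audible: bool


@lru_cache(maxsize=8)
def _sos(spec: EardrumFilterSpec) -> np.ndarray:
    return sps.butter(
        spec.order, spec.band, btype="bandpass", fs=spec.sample_rate, output="sos"
    )


def _delayed(x: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return x
    out = np.zeros_like(x)
    out[n:] = x[:-n]
    return out


def eardrum_filter(
    signal: BinauralSignal, spec: EardrumFilterSpec = EardrumFilterSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Left and right eardrum vibration traces for one binaural window.

    Each side mixes its ipsilateral channel with the gained, delayed
    contralateral channel and passes the sum through the shared band-pass,
    so a phase lead on one side raises that side's output power.
    """
    if len(signal.left) < MIN_WINDOW:
        raise ValueError(
            f"window of {len(signal.left)} samples is shorter than the "
            f"filter settling length ({MIN_WINDOW})"
        )
    g, nd = spec.contra_gain, spec.contra_delay
    left_in = signal.left + g * _delayed(signal.right, nd)
    right_in = signal.right + g * _delayed(signal.left, nd)
    stacked = sps.sosfilt(_sos(spec), np.stack([left_in, right_in]), axis=-1)
    return stacked[0], stacked[1]


def _power(x: np.ndarray) -> float:
    """Mean-square power, excluding the filter settling transient."""
    if len(x) > MIN_WINDOW:
        x = x[MIN_WINDOW:]
    return float(np.mean(np.square(x)))


def auditory_cue(
    filtered: tuple[np.ndarray, np.ndarray], calib: float
) -> AuditoryCue:
    """Directional cue from the filtered pair: clipped dB power difference.

    ``x_a = clip((P_right - P_left in dB) / calib, -1, +1)``; zero (and
    inaudible) when the total output power is zero.  Positive means the
    target lies to the agent's right.
    """
    if calib <= 0:
        raise ValueError("calibration constant must be positive")
    left, right = filtered
    if len(left) != len(right):
        raise ValueError("filtered sequences must have equal length")
    p_l, p_r = _power(left), _power(right)
    if p_l + p_r == 0.0:
        return AuditoryCue(x_a=0.0, audible=False)
    dp_db = 10.0 * math.log10(p_r / p_l)
    return AuditoryCue(x_a=float(np.clip(dp_db / calib, -1.0, 1.0)), audible=True)


def _sweep_dp_db(
    spec: EardrumFilterSpec, params: AcousticParams, thetas: np.ndarray
) -> np.ndarray:
    """Noiseless dB power difference over a bearing sweep at the nominal tone."""
    out = np.empty(len(thetas))
    pose = Pose(0.0, 0.0, math.pi / 2.0)
    for i, th in enumerate(thetas):
        # place the target at unit range on the requested bearing
        pos = (math.sin(th), math.cos(th))
        state = TargetState(position=pos, sound_on=True, t=0)
        left, right = eardrum_filter(emit_binaural(state, pose, params), spec)
        p_l, p_r = _power(left), _power(right)
        out[i] = 10.0 * math.log10(p_r / p_l)
    return out


@lru_cache(maxsize=8)
def calibrate(
    spec: EardrumFilterSpec = EardrumFilterSpec(),
    params: AcousticParams = AcousticParams(),
) -> float:
    """Cue normalisation constant: max |dB difference| over the semicircle.

    Swept noiselessly over 181 bearings at the nominal tone frequency; the
    extremes sit at +/-90 degrees because the difference is monotone in
    ``sin(bearing)``, so the calibrated cue reaches exactly +/-1 there.
    """
    thetas = np.linspace(-math.pi / 2.0, math.pi / 2.0, 181)
    dp = _sweep_dp_db(spec, params, thetas)
    peak = float(np.max(np.abs(dp)))
    # below ~0.05 dB there is no usable binaural response to normalise by
    if peak <= 0.05:
        raise ValueError("degenerate eardrum filter spec: no binaural response")
    return peak


def magnitude_response_frame(
    spec: EardrumFilterSpec = EardrumFilterSpec(), n_points: int = 256
):
    """Magnitude response of the shared band-pass as a DataFrame.

    Columns ``frequency_hz`` and ``gain_db``; suitable for CSV export and
    inspection of the 1-4 kHz pass band.
    """
    import pandas as pd

    freqs = np.linspace(50.0, spec.sample_rate / 2.0 * 0.9, n_points)
    _, h = sps.sosfreqz(_sos(spec), worN=freqs, fs=spec.sample_rate)
    gain_db = 20.0 * np.log10(np.maximum(np.abs(h), 1e-12))
    return pd.DataFrame({"frequency_hz": freqs, "gain_db": gain_db})


def surrogate_cue(bearing: float) -> float:
    """Closed-form cue backend: ``sin(bearing)`` clamped to the semicircle."""
    th = max(-math.pi / 2.0, min(math.pi / 2.0, bearing))
    return math.sin(th)
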