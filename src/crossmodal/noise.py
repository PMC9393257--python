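"""Additive white Gaussian noise at a target SNR, cue variances, reliabilities.

Noise injection follows the "measured" convention: the noise variance is
``P / 10**(snr_db / 10)`` where ``P`` is the measured mean-square power of
the signal the noise is added to.  Auditory noise is applied to the raw
sinusoid windows before the periphery, with each window's own measured
power.  Visual noise is applied directly to the scalar visual cue; since
the cue unfolds one sample per step inside a closed loop, its measured
power is tracked causally (:class:`MeasuredPower` — the running mean
square of the ideal cue over the trial's detected steps so far).

Cue reliability is the inverse of the cue variance; normalised reliabilities
are each modality's share of the summed inverse variances:

    rel_a = (1/var_a) / (1/var_a + 1/var_v),   rel_v = 1 - rel_a
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeasuredPower",
    "NoiseSpec",
    "ReliabilityPair",
    "add_awgn",
    "cue_noise_sigma",
    "cue_variance",
    "normalized_reliabilities",
]


class MeasuredPower:
    """Causal running mean-square power of a scalar cue signal.

    Emulates the "measured" signal-power convention for a signal that is
    only revealed one sample per time step: the reference power at step t
    is the mean square of the ideal cue over the detected steps up to and
    including t.
    """

    def __init__(self) -> None:
        self._sum = 0.0
        self._n = 0

    def update(self, x: float) -> float:
        """Fold in one ideal cue sample and return the current mean square."""
        self._sum += x * x
        self._n += 1
        return self._sum / self._n


@dataclass(frozen=True)
class NoiseSpec:
    """Per-trial SNR assignment (dB) for the two sensory pathways."""

    snr_a_db: float
    snr_v_db: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.snr_a_db) and math.isfinite(self.snr_v_db)):
            raise ValueError("SNRs must be finite dB values")


@dataclass(frozen=True)
class ReliabilityPair:
    """Cue variances plus their normalised (simplex) reliabilities."""

    var_a: float
    var_v: float
    rel_a_norm: float
    rel_v_norm: float


def add_awgn(signal: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    """Return ``signal`` plus white Gaussian noise at the requested SNR.

    The noise variance is derived from the signal's own measured mean-square
    power, so a zero-power (silent) signal passes through unchanged.  The
    input array is not modified.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("signal must be nonempty")
    power = float(np.mean(np.square(signal)))
    if power == 0.0:
        return signal.copy()
    sigma = math.sqrt(power / 10.0 ** (snr_db / 10.0))
    return signal + rng.normal(0.0, sigma, size=signal.shape)


def cue_noise_sigma(snr_db: float, reference_power: float) -> float:
    """Noise standard deviation for scalar cue-level injection at ``snr_db``."""
    return math.sqrt(reference_power / 10.0 ** (snr_db / 10.0))


def cue_variance(series) -> float:
    """Unbiased (n-1 denominator) sample variance of a cue series."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two samples to estimate a variance")
    return float(np.var(arr, ddof=1))


def normalized_reliabilities(var_a: float, var_v: float) -> ReliabilityPair:
    """Normalised inverse-variance reliabilities of the two cues."""
    if var_a <= 0 or var_v <= 0:
        raise ValueError("variances must be strictly positive")
    inv_a, inv_v = 1.0 / var_a, 1.0 / var_v
    rel_a = inv_a / (inv_a + inv_v)
    return ReliabilityPair(var_a=var_a, var_v=var_v, rel_a_norm=rel_a, rel_v_norm=1.0 - rel_a)
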