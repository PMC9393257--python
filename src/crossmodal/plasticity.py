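"""Multisensory neuron and the gated crossmodal ICO learning rules.

A single multisensory neuron fuses the two directional cues into a motor
output:

    v = w_v * x_v + w_a * x_a

The synaptic weights adapt by input-correlation (ICO) learning, a
differential Hebbian rule in which each weight moves with the product of
its *own* cue and the time derivative of the *other* modality's cue
(heterosynaptic, crossmodal — there are no intramodal terms):

    dw_a = mu * x_a * dx_v/dt        (only while the target emits sound)
    dw_v = mu * x_v * dx_a/dt        (only while the target is visible)

The auditory gate is independent of visibility.  Weights stabilise only
when the companion cue is zero or constant in time, which in the closed
tracking loop happens as the agent centres the target in both receptive
fields.  Derivatives are first-order backward differences; the first frame
of a trial has zero derivatives.  No weight bounds are imposed; divergence
beyond |w| > 1e3 triggers a runtime warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

__all__ = [
    "CueFrame",
    "SynapticWeights",
    "cue_derivative",
    "integrate",
    "normalize_weights",
    "update_weights",
]

DIVERGENCE_LIMIT = 1.0e3


@dataclass(frozen=True)
class SynapticWeights:
    """The weight pair (w_a, w_v) and the shared learning rate mu."""

    w_a: float = 0.1
    w_v: float = 0.1
    mu: float = 0.09

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("learning rate must be non-negative")


@dataclass(frozen=True)
class CueFrame:
    """One time step's cues, their derivatives, and the two update gates."""

    x_a: float
    x_v: float
    dx_a: float = 0.0
    dx_v: float = 0.0
    gate_a: bool = True  # target emitted sound this step
    gate_v: bool = True  # target inside the visual receptive field
    t: int = 0


def integrate(w: SynapticWeights, frame: CueFrame) -> float:
    """Fused motor output ``v = w_v * x_v + w_a * x_a`` (pure function)."""
    return w.w_v * frame.x_v + w.w_a * frame.x_a


def cue_derivative(prev: float | None, curr: float, dt: float = 1.0) -> float:
    """Backward-difference cue derivative; zero on the first frame."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if prev is None:
        return 0.0
    return (curr - prev) / dt


def update_weights(w: SynapticWeights, frame: CueFrame) -> SynapticWeights:
    """Apply one gated crossmodal ICO update and return the new weights."""
    w_a = w.w_a + (w.mu * frame.x_a * frame.dx_v if frame.gate_a else 0.0)
    w_v = w.w_v + (w.mu * frame.x_v * frame.dx_a if frame.gate_v else 0.0)
    if max(abs(w_a), abs(w_v)) > DIVERGENCE_LIMIT:
        warnings.warn(
            f"synaptic weights diverging (w_a={w_a:.3g}, w_v={w_v:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return replace(w, w_a=w_a, w_v=w_v)


def normalize_weights(w: SynapticWeights) -> tuple[float, float]:
    """Simplex-normalised weights ``(w_a, w_v) / (w_a + w_v)``.

    The same normalisation as the reliability simplex, making learned
    weights commensurable with normalised cue reliabilities.
    """
    total = w.w_a + w.w_v
    if total == 0:
        raise ValueError("cannot normalise weights summing to zero")
    return w.w_a / total, w.w_v / total
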