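# Methods

## The model

A single multisensory neuron receives two scalar directional cues per
simulation time step and emits a motor output `v = w_v·x_v + w_a·x_a`. The
output is assigned to the two wheels of a differential-drive agent with
equal magnitude and opposite sign (`|v_l| = |v_r| = |v|`), so the agent
only rotates on the spot, turning toward the side the fused cue points at.
The synaptic weights adapt by crossmodal ICO learning — each weight moves
with the product of its own cue and the backward-difference time derivative
of the other modality's cue, scaled by a shared learning rate μ:

    δw_a = μ · x_a · Δx_v     gated on sound emission,
    δw_v = μ · x_v · Δx_a     gated on target visibility.

There are no intramodal terms and no weight bounds; weights stabilise only
when the companion cue is zero or constant, which the closed tracking loop
approaches as the target is centred in both receptive fields. The per-step
order is fixed: sense → differentiate → update weights → integrate → act.

Because the rules are driven by cue *dynamics*, the intermittent auditory
cue (random duty cycle: off 5–10 steps, on 10–15 steps) injects large
on/offset transients into Δx_a, which preferentially pumps the visual
weight; this is why, at equal SNRs, `w_v` rises above `w_a`, and why the
auditory weight overtakes only when the auditory cue is far cleaner than
the visual one.

## Sensory peripheries

**Auditory.** The target emits two equal-amplitude sinusoids (f = 2.2 kHz,
amplitude 1, 512-sample windows at 44.1 kHz per time step) whose interaural
phase offset is δϕ = 2π·f·d·sin(θ)/c with sensor separation d = 13 mm and
c = 340 m/s. Each eardrum is modelled as a pressure-difference receiver:
the ipsilateral channel plus the contralateral channel through an internal
path with gain −0.6 and a 4-sample delay, both through a shared 4th-order
Butterworth band-pass (1–4 kHz). In steady state the output powers are
`1 + g² + 2g·cos(2πf·n_d/f_s ± δϕ)`, so the dB power difference is odd and
monotone in bearing and its frequency response peaks at ≈2.2 kHz, falling
off toward the band edges. The cue is that dB difference divided by a
calibration constant (the maximal noiseless difference over a 181-point
bearing sweep at the nominal tone, computed once and cached) and clipped to
[−1, +1]; powers are measured after discarding a 128-sample filter-settling
transient. Gain and delay of the contralateral path were fixed analytically
from the stated response properties (peak near 2.2 kHz, odd monotone
saturating cue); no vibrometry data is used. A closed-form surrogate
backend (`x_a = sin θ` with cue-level noise) is selectable by config and
all downstream modules are backend-agnostic; note the surrogate applies
noise without any spectral filtering and becomes unusably noisy below
about 9 dB.

**Visual.** The field is a head-centred wedge 57° wide and 4 m deep
(Kinect-like). Inside, the bearing maps linearly onto [−1, +1] (boundaries
inclusive); outside, the cue is exactly zero — a non-detection, not a
measurement.

## Noise

SNRs are assigned per trial and per modality in dB using the "measured"
convention: noise variance `P / 10^(SNR/10)` with `P` the measured
mean-square power of the signal the noise enters. Auditory noise is white
Gaussian on the raw sinusoid windows (each window's own power; silence
passes through untouched, so off-steps give an exact zero cue). Visual
noise enters the scalar cue directly, only while the target is visible; its
reference power is the causal running mean square of the ideal visible cue
over the trial so far, the closest per-step analogue of measuring the
power of the very signal the noise is added to. A fixed reference power
was considered and rejected: calibrated to the full field it makes the
visual cue several times noisier than the auditory cue at equal assigned
SNR (inverting the modality asymmetry) and destabilises tracking at 3 dB.

Cue variance per trial is the unbiased sample variance over steps where the
cue's own gate was active; zeros from non-detection are structural and are
excluded. Reliabilities are normalised inverse variances.

## Agent and arena

Standard ICC differential-drive kinematics with wheel separation
l = 16 cm: ω = (v_r − v_l)/l, D = (l/2)(v_r + v_l)/(v_r − v_l); pure
rotation and straight-line motion are exact limits. Positive fused output
(target right) commands a clockwise rotation, closing a negative-feedback
loop around the bearing error.

Two scale parameters anchor the task, both configurable:

* `speed_scale = 0.01` maps the nominal per-step target speeds (along-track
  U[0, 10], cross-track U[0, 4] with random signs, redrawn every 5–10 and
  0–5 steps respectively) onto arena metres. The nominal speed units and
  the 4 m visual depth are mutually inconsistent if taken literally; this
  scale makes one 200-step right-to-left crossing span ≈10 m at a 2.5 m
  standoff, keeping the target within sensing range for a usable fraction
  of each trial. Schedules store the nominal values unchanged.
* `dt = 0.05` is the kinematic integration step — the fraction of one
  sensory time step over which the wheel commands act. Cue derivatives use
  the sensory step itself. With `|v_l| = |v_r| = |v|` taken literally, the
  discrete orientation loop has gain 2|v|·dt/l per step; dt = 0.05 keeps
  the loop stable (no oscillatory weight runaway) over the weight range the
  learning visits (≈0.1–0.7) while remaining responsive. Larger steps
  (0.07–0.1) produced weight divergence in low-SNR sessions; this mirrors
  the oscillation-versus-sluggishness trade-off inherent to the reflexive
  controller.

Every trial starts with the agent at the origin pointing straight ahead
(+y) and the target entering at (5, 2.5) m on its right. An optional spawn
box can randomise the entry point; it is off by default because randomised
entries (especially beyond the visual depth) bias early-trial learning
toward the always-available auditory channel.

## Protocols and evaluation

Sessions run 20 trials (200 steps each) with weight carry-over, μ = 0.09,
initial weights 0.1. Protocol sweeps: (a) visual SNR fixed at 3 dB,
auditory 6–21 dB in 3 dB steps; (b) the converse; (c) both equal, 3–21 dB;
plus a 100-trial low-SNR protocol at μ = 0.01.

The MLE comparison first learns session-end weights for every SNR condition
the randomized evaluation can draw, then runs 50 evaluation trials with
learning disabled. Each trial draws its SNRs (either both equal from
{3, 9, 12, 15, 18, 21} dB, or one random modality from that set with the
other at 3 dB) and runs the closed loop twice over the *same* trajectory
and duty cycle with independent noise: once with the learned normalised
weights, once with weights set to the normalised reliabilities measured
from the first run's gated cue variances. The per-trial "average relative
target location" is the time-average of the fused location signal over
steps where at least one detection gate was active; unisensory estimates
average the corresponding cue over its own gate. An accuracy variant
(1 − mean |signal|, higher = lower localization error) is computed
alongside and is the statistic used for the Welch t-tests, whose direction
("fused estimate significantly higher") only makes sense on an
accuracy-like scale. The model-vs-MLE regression uses iteratively
reweighted least squares with Tukey bisquare weights (tuning constant
4.685, residuals scaled by 1.4826·MAD, ≤50 iterations, coefficient
tolerance 1e−8; statsmodels RLM underneath) with r², SSE and RMSE computed
on the weighted fit. Trials in which a crossing never intersects a
receptive field (no usable cue statistics) are redrawn deterministically.

Sharing the world streams between the paired runs is essential: the
across-trial spread of the location estimates is carried almost entirely by
the shared trajectory and SNR condition, and it is this shared component
that the regression measures. Seeding is explicit throughout — a master
seed splits into four substreams per trial (trajectory, duty cycle,
auditory noise, visual noise) via stateless spawn-key derivation, so any
trial or session is exactly replayable.

## What the synthetic world does and does not emulate

The generator reproduces the stated stimulus statistics: uniform random
zig-zag speeds with the stated hold ranges, the stated emission duty cycle,
sinusoidal binaural signals with geometry-exact phase offsets, and
independently manipulable per-modality SNRs with trial-to-trial variance
variability. It does not model distance attenuation, reverberation,
interaural level differences, front–back ambiguity (bearings are clamped to
the frontal semicircle), visual image formation, or target
detection/recognition. Passing tests therefore demonstrate properties of
the learning rule and the integration scheme under idealised geometry and
additive Gaussian noise — not robustness to real acoustic environments or
real visual clutter.

## Numerical choices and degenerate inputs

Calibration below 0.05 dB raises (no usable binaural response); windows
shorter than 128 samples raise (filter settling); variances require ≥2
gated samples; reliabilities require strictly positive variances; weight
normalisation requires a nonzero weight sum; |w| > 10³ triggers a runtime
warning but trials complete. Problem sizes in the test suite and the
acceptance script (200-step trials, 20-trial sessions, 50 evaluation
trials, 5–10 replicate seeds) were chosen as the smallest sizes at which
the session-level claims are stable across seeds.

## Known limitations

* The arena/speed scale and kinematic step are package choices where the
  source material is silent or self-inconsistent; session-level quantities
  (absolute weight magnitudes, exact crossover SNR of the auditory/visual
  dominance reversal) depend on them. The qualitative structure —
  reliability tracking with a persistent offset, visual dominance at equal
  SNR, reversal only at large auditory advantage, fused-variance
  reduction — is stable across seeds at the defaults.
* The learned normalised weights approach but never equal the normalised
  reliabilities; the offset does not vanish with more trials. This is a
  property of the learning rule, not a bug.
* The dominance crossover occurs at a smaller auditory SNR advantage than
  the +15 dB reported for the original system; the property tests
  therefore check the two extreme conditions rather than the exact
  crossover point.
* No causal inference: the agent always integrates both cues, even when
  only one carries information.
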