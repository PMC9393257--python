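# crossmodal

Embodied crossmodal synaptic plasticity for audio-visual cue integration.

A simulated differential-drive agent tracks an audio-visual target that
crosses its field of view along random zig-zag paths while emitting an
intermittent 2.2 kHz tone. Two head-centred directional cues are extracted
each time step — an auditory cue `x_a ∈ [−1, +1]` from the binaural power
difference of a lizard-ear-style band-pass filter pair, and a visual cue
`x_v ∈ [−1, +1]` from the target's bearing inside a 57°-wide, 4 m-deep
receptive field. A single multisensory neuron fuses them into a motor
output,

```
v = w_v · x_v + w_a · x_a ,
```

which drives on-the-spot orientation toward the target. The synaptic
weights adapt by gated crossmodal ICO (input-correlation, differential
Hebbian) learning,

```
δw_a = μ · x_a · dx_v/dt        (only while the target emits sound)
δw_v = μ · x_v · dx_a/dt        (only while the target is visible)
```

so each weight moves with the correlation between its own cue and the
*other* modality's dynamics. Over repeated tracking trials under
manipulated signal-to-noise ratios the normalised weights come to track the
normalised cue reliabilities

```
rel_a = (1/σ_a²) / (1/σ_a² + 1/σ_v²) ,    rel_v = 1 − rel_a ,
```

which is the maximum-likelihood (inverse-variance) weighting for
independent Gaussian cues. The package also implements the MLE control
model, per-trial target-location estimates, Tukey-bisquare robust
regression of the learned model against the MLE model, and one-tailed Welch
t-tests of fused versus unisensory estimates.

Who this is for: computational neuroscientists and biorobotics researchers
studying the development of reliability-weighted multisensory integration,
and anyone needing a compact, fully seeded closed-loop testbed for
correlation-based cross-modal learning rules.

## Worked example

Run one 20-trial learning session with a noisy auditory cue (3 dB) and a
clean visual cue (21 dB); weights carry over between trials:

```python
from crossmodal.experiment import build_session, run_session

session = run_session(build_session(snr_a_db=3.0, snr_v_db=21.0, seed=42, n_trials=20))
w = session.final_weights
summary = session.trial_summaries()
print(f"final weights:      w_a = {w.w_a:.4f}, w_v = {w.w_v:.4f}")
print(f"normalized weights: w_a = {w.w_a/(w.w_a+w.w_v):.4f}, w_v = {w.w_v/(w.w_a+w.w_v):.4f}")
print(f"mean normalized reliabilities: rel_a = {summary.rel_a_norm.mean():.4f}, "
      f"rel_v = {summary.rel_v_norm.mean():.4f}")
```

prints

```
final weights:      w_a = 0.1234, w_v = 0.3213
normalized weights: w_a = 0.2775, w_v = 0.7225
mean normalized reliabilities: rel_a = 0.1728, rel_v = 0.8272
```

The agent learned to weight the clean visual cue about 2.6× more than the
noisy auditory cue, and the learned normalised weights sit close to (with a
persistent finite offset from) the measured normalised reliabilities —
reliability-weighted integration acquired purely from sensorimotor
experience, without ever being told the noise levels.

The same protocols are available from the shell:

```sh
crossmodal run-session --protocol a --seed 0 --out out/sessions
crossmodal evaluate --n-trials 50 --seed 0 --out out/eval
crossmodal plot weights --protocol c --seed 0 --out out/figs
```

`evaluate` prints the robust-regression summary (`p1`, `p2`, `r2`, `sse`,
`rmse`) of the learned model against the MLE control and the four Welch
t-tests of fused versus unisensory accuracy, and writes the per-trial
estimates, variance table and t-test table as CSV/JSON.

## Layout

| module | contents |
| --- | --- |
| `crossmodal.world` | target trajectories, sound duty cycle, binaural tone synthesis |
| `crossmodal.auditory` | eardrum band-pass filter pair, auditory cue, calibration |
| `crossmodal.visual` | geometric visual cue and receptive-field gating |
| `crossmodal.noise` | AWGN at target SNR, cue variances, normalised reliabilities |
| `crossmodal.agent` | differential-drive kinematics, reflexive turn controller |
| `crossmodal.plasticity` | multisensory neuron and the crossmodal ICO rules |
| `crossmodal.experiment` | closed-loop trials, sessions, SNR protocols |
| `crossmodal.evaluation` | MLE control, estimates, robust regression, Welch tests |
| `crossmodal.config` / `crossmodal.cli` | YAML configuration and the `crossmodal` CLI |

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.
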