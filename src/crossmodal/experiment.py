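"""Closed-loop tracking trials and multi-trial learning sessions.

One trial couples every stage of the model: the world advances the target
and emits (or withholds) the binaural tone; the peripheries extract noisy
directional cues; the crossmodal ICO rules update the synaptic weights; the
multisensory neuron fuses the cues into a motor output; and the agent
rotates on the spot toward the fused direction.  Per-step update order is
fixed: sense -> differentiate -> update weights -> integrate -> act.

Sessions chain trials with weight carry-over (weights are never reset
between trials) and reproduce the three SNR protocols:

* ``a`` — visual SNR fixed at 3 dB, auditory SNR swept 6..21 dB (step 3);
* ``b`` — auditory SNR fixed at 3 dB, visual SNR swept 6..21 dB;
* ``c`` — both SNRs identical, swept 3..21 dB;
* ``low-snr`` — the 100-trial low-SNR protocol at learning rate 0.01.

Randomness is explicit: a master trial seed is split into four independent
substreams (trajectory, duty cycle, auditory noise, visual noise), and a
session seed spawns per-trial seeds, so identical seeds give bit-identical
logs while noise distributions stay independent across trials.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agent import (
    WHEEL_SEPARATION_M,
    Pose,
    bearing_to,
    command_from_speed,
    forward_kinematics,
)
from .auditory import (
    EardrumFilterSpec,
    auditory_cue,
    calibrate,
    eardrum_filter,
    surrogate_cue,
)
from .noise import (
    MeasuredPower,
    add_awgn,
    cue_noise_sigma,
    cue_variance,
    normalized_reliabilities,
)
from .plasticity import (
    CueFrame,
    SynapticWeights,
    cue_derivative,
    integrate,
    normalize_weights,
    update_weights,
)
from .visual import VisualField, visual_cue
from .world import (
    AcousticParams,
    BinauralSignal,
    TargetState,
    emit_binaural,
    generate_trajectory,
    sound_duty_schedule,
    step_target,
)

__all__ = [
    "SimConfig",
    "SessionLog",
    "TrialConfig",
    "TrialLog",
    "build_session",
    "learn_weight_table",
    "normalize_weights",
    "protocol_conditions",
    "run_protocol",
    "run_session",
    "run_trial",
]

SNR_SWEEP_DB = (6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
SNR_EQUAL_SWEEP_DB = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)


@dataclass(frozen=True)
class SimConfig:
    """Fixed physical/numerical parameters shared by every trial.

    ``speed_scale`` maps the nominal per-step speed units onto arena metres
    so one ~200-step crossing stays commensurate with the 4 m visual depth.
    ``dt`` is the kinematic integration step (fraction of one sensory time
    step over which wheel commands act); cue derivatives always use the
    sensory step itself (``deriv_dt``).
    """

    acoustics: AcousticParams = AcousticParams()
    filter_spec: EardrumFilterSpec = EardrumFilterSpec()
    visual: VisualField = VisualField()
    wheel_separation: float = WHEEL_SEPARATION_M
    dt: float = 0.05
    deriv_dt: float = 1.0
    speed_scale: float = 0.01
    #: every trial's crossing enters at the agent's front-right, within reach
    #: of both receptive fields, so each modality contributes from early on
    target_start: tuple[float, float] = (5.0, 2.5)
    #: optional spawn box ((x_lo, x_hi), (y_lo, y_hi)); when set, each trial
    #: draws its own start point instead of using ``target_start``
    spawn_box: tuple[tuple[float, float], tuple[float, float]] | None = None
    heading0: float = math.pi / 2.0
    auditory_backend: str = "filter"  # "filter" | "surrogate"
    auditory_calib: float | None = None  # None -> auto (calibration sweep)


@dataclass(frozen=True)
class TrialConfig:
    """Full parameterization of one tracking trial."""

    snr_a_db: float
    snr_v_db: float
    seed: int | np.random.SeedSequence
    n_steps: int = 200
    mu: float = 0.09
    learning_enabled: bool = True
    noise_seed: int | np.random.SeedSequence | None = None
    sim: SimConfig = SimConfig()

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class TrialLog:
    """Per-step records plus recomputable per-trial summaries."""

    records: pd.DataFrame
    summary: dict
    config: TrialConfig

    @property
    def final_weights(self) -> SynapticWeights:
        last = self.records.iloc[-1]
        return SynapticWeights(
            w_a=float(last["w_a"]), w_v=float(last["w_v"]), mu=self.config.mu
        )

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def summary_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary, indent=2))


@dataclass
class SessionLog:
    """Ordered trial logs for one session, with carried weights."""

    trials: list[TrialLog]
    condition: dict = field(default_factory=dict)

    @property
    def final_weights(self) -> SynapticWeights:
        return self.trials[-1].final_weights

    def weight_evolution(self) -> pd.DataFrame:
        """Per-step weight trajectory concatenated across trials."""
        frames = []
        for k, trial in enumerate(self.trials):
            df = trial.records[["t", "w_a", "w_v"]].copy()
            df.insert(0, "trial", k)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out["step"] = np.arange(len(out))
        return out

    def trial_summaries(self) -> pd.DataFrame:
        return pd.DataFrame([t.summary for t in self.trials])

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.weight_evolution().to_csv(out_dir / "weights.csv", index=False)
        self.trial_summaries().to_csv(out_dir / "trials.csv", index=False)
        (out_dir / "condition.json").write_text(json.dumps(self.condition, indent=2))


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _children(ss: np.random.SeedSequence, n: int) -> list[np.random.SeedSequence]:
    """Stateless spawn: the same parent always yields the same children.

    ``SeedSequence.spawn`` advances an internal counter, which would make a
    rerun of the same trial config draw different substreams; deriving the
    spawn keys explicitly keeps trial configs replayable.
    """
    return [
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (i,))
        for i in range(n)
    ]


def _auditory_calibration(sim: SimConfig) -> float:
    if sim.auditory_calib is not None:
        return sim.auditory_calib
    return calibrate(sim.filter_spec, sim.acoustics)


def run_trial(config: TrialConfig, w: SynapticWeights | None = None) -> TrialLog:
    """Run one closed-loop tracking trial; deterministic given its seeds.

    ``noise_seed`` (if given) decouples the sensor-noise substreams from the
    world substreams, so two runs can share a trajectory and duty cycle
    while experiencing independent noise.
    """
    sim = config.sim
    if w is None:
        w = SynapticWeights(mu=config.mu)
    else:
        w = replace(w, mu=config.mu)

    world_ss = _seed_sequence(config.seed)
    traj_ss, duty_ss, a_noise_ss, v_noise_ss = _children(world_ss, 4)
    if config.noise_seed is not None:
        a_noise_ss, v_noise_ss = _children(_seed_sequence(config.noise_seed), 2)
    rng_traj = np.random.default_rng(traj_ss)
    rng_duty = np.random.default_rng(duty_ss)
    rng_a = np.random.default_rng(a_noise_ss)
    rng_v = np.random.default_rng(v_noise_ss)

    schedule = generate_trajectory(config.n_steps, rng_traj)
    duty = sound_duty_schedule(config.n_steps + 1, rng_duty)

    use_filter = sim.auditory_backend == "filter"
    if use_filter:
        calib = _auditory_calibration(sim)
    # running measured powers of the ideal scalar cues (cue-level injection)
    power_v = MeasuredPower()
    power_a = MeasuredPower()  # surrogate backend only

    pose = Pose(0.0, 0.0, sim.heading0)
    start = sim.target_start
    if sim.spawn_box is not None:
        (x_lo, x_hi), (y_lo, y_hi) = sim.spawn_box
        start = (float(rng_traj.uniform(x_lo, x_hi)), float(rng_traj.uniform(y_lo, y_hi)))
    state = TargetState(position=start, sound_on=duty.sound_on(0), t=0)

    prev_xa: float | None = None
    prev_xv: float | None = None
    cols: dict[str, list] = {k: [] for k in (
        "t", "x", "y", "theta", "target_x", "target_y", "bearing",
        "x_a", "x_v", "dx_a", "dx_v", "gate_a", "gate_v", "w_a", "w_v", "v",
    )}

    for t in range(config.n_steps):
        bearing = bearing_to(pose, state.position)

        vc = visual_cue(state, pose, sim.visual)
        x_v = vc.x_v
        if vc.visible:
            ref = power_v.update(vc.x_v)
            x_v += rng_v.normal(0.0, cue_noise_sigma(config.snr_v_db, ref))

        if use_filter:
            sig = emit_binaural(state, pose, sim.acoustics)
            if sig.is_silent:
                x_a, audible = 0.0, False
            else:
                noisy = BinauralSignal(
                    left=add_awgn(sig.left, config.snr_a_db, rng_a),
                    right=add_awgn(sig.right, config.snr_a_db, rng_a),
                    sample_rate=sig.sample_rate,
                )
                cue = auditory_cue(eardrum_filter(noisy, sim.filter_spec), calib)
                x_a, audible = cue.x_a, cue.audible
        else:
            if state.sound_on:
                ideal = surrogate_cue(bearing)
                ref = power_a.update(ideal)
                x_a = float(np.clip(
                    ideal + rng_a.normal(0.0, cue_noise_sigma(config.snr_a_db, ref)),
                    -1.0, 1.0,
                ))
                audible = True
            else:
                x_a, audible = 0.0, False

        dx_a = cue_derivative(prev_xa, x_a, sim.deriv_dt)
        dx_v = cue_derivative(prev_xv, x_v, sim.deriv_dt)
        prev_xa, prev_xv = x_a, x_v

        frame = CueFrame(
            x_a=x_a, x_v=x_v, dx_a=dx_a, dx_v=dx_v,
            gate_a=state.sound_on, gate_v=vc.visible, t=t,
        )
        if config.learning_enabled:
            w = update_weights(w, frame)
        v = integrate(w, frame)

        cols["t"].append(t)
        cols["x"].append(pose.x)
        cols["y"].append(pose.y)
        cols["theta"].append(pose.theta)
        cols["target_x"].append(state.position[0])
        cols["target_y"].append(state.position[1])
        cols["bearing"].append(bearing)
        cols["x_a"].append(x_a)
        cols["x_v"].append(x_v)
        cols["dx_a"].append(dx_a)
        cols["dx_v"].append(dx_v)
        cols["gate_a"].append(state.sound_on)
        cols["gate_v"].append(vc.visible)
        cols["w_a"].append(w.w_a)
        cols["w_v"].append(w.w_v)
        cols["v"].append(v)

        cmd = command_from_speed(v, sim.wheel_separation)
        pose = forward_kinematics(pose, cmd, sim.dt)
        state = step_target(state, schedule, duty, sim.speed_scale)

    records = pd.DataFrame(cols)
    summary = _trial_summary(records, config, w)
    return TrialLog(records=records, summary=summary, config=config)


def _trial_summary(records: pd.DataFrame, config: TrialConfig, w: SynapticWeights) -> dict:
    """Gated cue variances, normalised reliabilities, and final weights.

    Variances are taken over steps where the cue's own detection gate was
    active; zeros from non-detection are structural, not noise.
    """
    xa = records.loc[records["gate_a"], "x_a"].to_numpy()
    xv = records.loc[records["gate_v"], "x_v"].to_numpy()
    var_a = cue_variance(xa) if xa.size >= 2 else float("nan")
    var_v = cue_variance(xv) if xv.size >= 2 else float("nan")
    if var_a > 0 and var_v > 0:
        rel = normalized_reliabilities(var_a, var_v)
        rel_a, rel_v = rel.rel_a_norm, rel.rel_v_norm
    else:
        rel_a = rel_v = float("nan")
    try:
        wa_n, wv_n = normalize_weights(w)
    except ValueError:
        wa_n = wv_n = float("nan")
    return {
        "snr_a_db": config.snr_a_db,
        "snr_v_db": config.snr_v_db,
        "n_steps": config.n_steps,
        "mu": config.mu,
        "var_a": var_a,
        "var_v": var_v,
        "rel_a_norm": rel_a,
        "rel_v_norm": rel_v,
        "w_a_final": w.w_a,
        "w_v_final": w.w_v,
        "w_a_norm": wa_n,
        "w_v_norm": wv_n,
        "mean_abs_bearing": float(records["bearing"].abs().mean()),
    }


def build_session(
    snr_a_db: float,
    snr_v_db: float,
    seed: int | np.random.SeedSequence,
    n_trials: int = 20,
    n_steps: int = 200,
    mu: float = 0.09,
    sim: SimConfig = SimConfig(),
    learning_enabled: bool = True,
) -> list[TrialConfig]:
    """Per-trial configs for one SNR condition, with spawned trial seeds."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    trial_seeds = _children(_seed_sequence(seed), n_trials)
    return [
        TrialConfig(
            snr_a_db=snr_a_db, snr_v_db=snr_v_db, seed=s, n_steps=n_steps,
            mu=mu, learning_enabled=learning_enabled, sim=sim,
        )
        for s in trial_seeds
    ]


def run_session(
    schedule: list[TrialConfig], w_init: SynapticWeights | None = None
) -> SessionLog:
    """Run trials sequentially, carrying weights from one trial to the next."""
    if not schedule:
        raise ValueError("session schedule must be nonempty")
    w = w_init if w_init is not None else SynapticWeights(mu=schedule[0].mu)
    trials: list[TrialLog] = []
    for config in schedule:
        log = run_trial(config, w)
        w = log.final_weights
        trials.append(log)
    first = schedule[0]
    return SessionLog(
        trials=trials,
        condition={
            "snr_a_db": first.snr_a_db,
            "snr_v_db": first.snr_v_db,
            "n_trials": len(schedule),
            "n_steps": first.n_steps,
            "mu": first.mu,
        },
    )


def protocol_conditions(protocol: str) -> list[tuple[float, float]]:
    """(snr_a_db, snr_v_db) pairs for the named protocol."""
    if protocol == "a":
        return [(s, 3.0) for s in SNR_SWEEP_DB]
    if protocol == "b":
        return [(3.0, s) for s in SNR_SWEEP_DB]
    if protocol == "c":
        return [(s, s) for s in SNR_EQUAL_SWEEP_DB]
    if protocol == "low-snr":
        return [(3.0, 6.0), (6.0, 3.0)]
    raise ValueError(f"unknown protocol {protocol!r}")


def run_protocol(
    protocol: str,
    seed: int,
    n_trials: int | None = None,
    n_steps: int = 200,
    sim: SimConfig = SimConfig(),
) -> dict[tuple[float, float], SessionLog]:
    """Run one full protocol: a session per SNR condition.

    The ``low-snr`` protocol defaults to 100 trials at learning rate 0.01;
    the others to 20 trials at 0.09.
    """
    mu = 0.01 if protocol == "low-snr" else 0.09
    if n_trials is None:
        n_trials = 100 if protocol == "low-snr" else 20
    conditions = protocol_conditions(protocol)
    cond_seeds = _children(_seed_sequence(seed), len(conditions))
    out: dict[tuple[float, float], SessionLog] = {}
    for (snr_a, snr_v), css in zip(conditions, cond_seeds):
        schedule = build_session(
            snr_a, snr_v, css, n_trials=n_trials, n_steps=n_steps, mu=mu, sim=sim
        )
        out[(snr_a, snr_v)] = run_session(schedule)
    return out


def learn_weight_table(
    conditions: list[tuple[float, float]],
    seed: int | np.random.SeedSequence,
    n_trials: int = 20,
    n_steps: int = 200,
    mu: float = 0.09,
    sim: SimConfig = SimConfig(),
) -> dict[tuple[float, float], dict]:
    """Session-end weights (raw and normalised) per SNR condition."""
    cond_seeds = _children(_seed_sequence(seed), len(conditions))
    table: dict[tuple[float, float], dict] = {}
    for (snr_a, snr_v), css in zip(conditions, cond_seeds):
        schedule = build_session(
            snr_a, snr_v, css, n_trials=n_trials, n_steps=n_steps, mu=mu, sim=sim
        )
        session = run_session(schedule)
        w = session.final_weights
        wa_n, wv_n = normalize_weights(w)
        table[(snr_a, snr_v)] = {
            "w_a": w.w_a, "w_v": w.w_v, "w_a_norm": wa_n, "w_v_norm": wv_n,
        }
    return table
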