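"""Plain-text (YAML) configuration for trials and sessions.

Recognised keys (all optional; unset keys fall back to the defaults that
define the standard task conditions)::

    world:     n_steps, seed, speed_scale, target_start, heading0
    acoustics: f, d, c, amplitude, sample_rate, window
    auditory:  backend (filter | surrogate), calib (auto | number)
    visual:    width_deg, depth_m
    noise:     snr_a_db, snr_v_db, seed
    agent:     l_m, dt
    learning:  mu, w_init, enabled
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .agent import WHEEL_SEPARATION_M
from .auditory import EardrumFilterSpec
from .experiment import SimConfig, TrialConfig
from .plasticity import SynapticWeights
from .visual import VisualField
from .world import AcousticParams

__all__ = ["load_config", "sim_config_from", "trial_config_from", "weights_from"]


def load_config(path) -> dict:
    """Read a YAML config file into a nested dict (empty file -> {})."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return data or {}


def sim_config_from(cfg: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a nested config dict."""
    world = cfg.get("world", {})
    ac = cfg.get("acoustics", {})
    aud = cfg.get("auditory", {})
    vis = cfg.get("visual", {})
    agent = cfg.get("agent", {})
    calib = aud.get("calib", "auto")
    acoustics = AcousticParams(
        f=float(ac.get("f", 2200.0)),
        d=float(ac.get("d", 0.013)),
        c=float(ac.get("c", 340.0)),
        amplitude=float(ac.get("amplitude", 1.0)),
        sample_rate=float(ac.get("sample_rate", 44100.0)),
        window=int(ac.get("window", 512)),
    )
    return SimConfig(
        acoustics=acoustics,
        filter_spec=EardrumFilterSpec(sample_rate=acoustics.sample_rate),
        visual=VisualField(
            width_deg=float(vis.get("width_deg", 57.0)),
            depth_m=float(vis.get("depth_m", 4.0)),
        ),
        wheel_separation=float(agent.get("l_m", WHEEL_SEPARATION_M)),
        dt=float(agent.get("dt", 0.1)),
        speed_scale=float(world.get("speed_scale", 0.01)),
        target_start=tuple(world.get("target_start", (5.0, 2.5))),
        heading0=float(world.get("heading0", math.pi / 2.0)),
        auditory_backend=str(aud.get("backend", "filter")),
        auditory_calib=None if calib == "auto" else float(calib),
    )


def weights_from(cfg: dict) -> SynapticWeights:
    learning = cfg.get("learning", {})
    w_init = learning.get("w_init", (0.1, 0.1))
    if isinstance(w_init, (int, float)):
        w_init = (w_init, w_init)
    return SynapticWeights(
        w_a=float(w_init[0]), w_v=float(w_init[1]),
        mu=float(learning.get("mu", 0.09)),
    )


def trial_config_from(cfg: dict) -> TrialConfig:
    """Build a :class:`TrialConfig` from a nested config dict."""
    world = cfg.get("world", {})
    noise = cfg.get("noise", {})
    learning = cfg.get("learning", {})
    return TrialConfig(
        snr_a_db=float(noise.get("snr_a_db", 3.0)),
        snr_v_db=float(noise.get("snr_v_db", 3.0)),
        seed=int(noise.get("seed", world.get("seed", 0))),
        n_steps=int(world.get("n_steps", 200)),
        mu=float(learning.get("mu", 0.09)),
        learning_enabled=bool(learning.get("enabled", True)),
        sim=sim_config_from(cfg),
    )
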