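"""MLE control model, per-trial estimates, robust regression, Welch t-tests.

The learned model is benchmarked against maximum-likelihood estimation
(MLE): a control in which the synaptic weights are fixed to the normalised
inverse-variance reliabilities of the cues, the statistically optimal
weighting for independent Gaussian cues (fused variance
``var_a * var_v / (var_a + var_v)``, never above either unisensory
variance).

Each evaluation trial runs the closed loop twice with learning disabled —
once with the learned session-end normalised weights, once with MLE weights
— over a shared target trajectory and duty cycle but independent noise.
Per-trial "average relative target location" estimates (gated time-averages
of the fused or unisensory location signal; or the accuracy variant
``1 - mean|.|``) feed a robust bisquare linear regression of model against
MLE, and one-tailed Welch t-tests of each fused model against each
unisensory estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .experiment import (
    SimConfig,
    TrialConfig,
    TrialLog,
    learn_weight_table,
    run_trial,
)
from .noise import ReliabilityPair, normalized_reliabilities
from .plasticity import SynapticWeights

__all__ = [
    "EVAL_SNR_SET_DB",
    "LocationEstimate",
    "RegressionFit",
    "TTestResult",
    "evaluation_conditions",
    "mle_comparison_experiment",
    "mle_weights",
    "robust_linear_fit",
    "run_mle_comparison",
    "trial_location_estimate",
    "variance_comparison",
    "welch_t_test",
]

#: SNR values (dB) drawn for the randomized fixed-weight evaluation trials.
EVAL_SNR_SET_DB = (3.0, 9.0, 12.0, 15.0, 18.0, 21.0)

MODES = ("fused-learned", "fused-mle", "auditory-only", "visual-only")


@dataclass(frozen=True)
class LocationEstimate:
    """One trial's average relative target-location estimate."""

    value: float
    mode: str


@dataclass(frozen=True)
class RegressionFit:
    """First-order robust (bisquare) fit ``f(x) = p1*x + p2``."""

    p1: float
    p2: float
    r2: float
    sse: float
    rmse: float
    weights: np.ndarray


@dataclass(frozen=True)
class TTestResult:
    """One-tailed (right) Welch test with Satterthwaite df."""

    t: float
    df: float
    p: float


def mle_weights(rel: ReliabilityPair) -> SynapticWeights:
    """Fixed MLE weights: each modality's normalised reliability; no learning."""
    return SynapticWeights(w_a=rel.rel_a_norm, w_v=rel.rel_v_norm, mu=0.0)


def trial_location_estimate(
    log: TrialLog,
    mode: str,
    weights: tuple[float, float] | SynapticWeights | None = None,
    kind: str = "location",
) -> LocationEstimate:
    """Per-trial estimate of average relative target location.

    Fused modes average ``w_v*x_v + w_a*x_a`` (with the mode's weights)
    over steps where at least one detection gate was active; unisensory
    modes average the corresponding cue over its own gated steps.  With
    ``kind="accuracy"`` the statistic is ``1 - mean|signal|`` instead, so
    higher values mean lower localization error.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    df = log.records
    if mode == "auditory-only":
        mask = df["gate_a"].to_numpy()
        signal = df["x_a"].to_numpy()
    elif mode == "visual-only":
        mask = df["gate_v"].to_numpy()
        signal = df["x_v"].to_numpy()
    else:
        if weights is None:
            raise ValueError("fused modes require an explicit weight pair")
        if isinstance(weights, SynapticWeights):
            w_a, w_v = weights.w_a, weights.w_v
        else:
            w_a, w_v = weights
        mask = (df["gate_a"] | df["gate_v"]).to_numpy()
        signal = (w_v * df["x_v"] + w_a * df["x_a"]).to_numpy()
    if not mask.any():
        raise ValueError(f"no gated steps for mode {mode!r}")
    gated = signal[mask]
    if kind == "location":
        value = float(np.mean(gated))
    elif kind == "accuracy":
        value = 1.0 - float(np.mean(np.abs(gated)))
    else:
        raise ValueError(f"unknown estimate kind {kind!r}")
    return LocationEstimate(value=value, mode=mode)


def evaluation_conditions() -> list[tuple[float, float]]:
    """All (snr_a, snr_v) pairs the randomized evaluation can draw.

    These are the conditions for which learned weights must exist: identical
    SNRs from the evaluation set, plus one modality from the set with the
    other fixed at 3 dB.
    """
    pairs = {(s, s) for s in EVAL_SNR_SET_DB}
    pairs |= {(s, 3.0) for s in EVAL_SNR_SET_DB}
    pairs |= {(3.0, s) for s in EVAL_SNR_SET_DB}
    return sorted(pairs)


def _draw_snrs(rng: np.random.Generator) -> tuple[float, float]:
    """One trial's SNR assignment per the stated randomization."""
    s = float(rng.choice(EVAL_SNR_SET_DB))
    if rng.random() < 0.5:  # condition (a): identical SNRs
        return s, s
    if rng.random() < 0.5:  # condition (b): one random modality vs 3 dB
        return s, 3.0
    return 3.0, s


def _group_label(snr_a: float, snr_v: float) -> str:
    if snr_v > snr_a:
        return "SNRv>SNRa"
    if snr_a > snr_v:
        return "SNRa>SNRv"
    return "SNRv=SNRa"


def run_mle_comparison(
    weight_table: dict[tuple[float, float], dict],
    seed: int | np.random.SeedSequence,
    n_trials: int = 50,
    n_steps: int = 200,
    sim: SimConfig = SimConfig(),
) -> pd.DataFrame:
    """Run the randomized fixed-weight evaluation trials.

    Per trial: draw SNRs, run the closed loop with the learned normalised
    weights for that condition, estimate cue reliabilities from that run's
    gated cue variances, then rerun with MLE weights over the same world.
    Returns one row per trial with location and accuracy estimates for all
    four modes.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    for k in range(n_trials):
        snr_a, snr_v = _draw_snrs(draw_rng)
        learned = weight_table[(snr_a, snr_v)]
        w_model = SynapticWeights(
            w_a=learned["w_a_norm"], w_v=learned["w_v_norm"], mu=0.0
        )
        # a crossing can, rarely, never intersect a receptive field; such a
        # trial has no usable cue statistics, so redraw its world
        for _attempt in range(20):
            world_ss, model_noise_ss, mle_noise_ss = ss.spawn(3)
            model_cfg = TrialConfig(
                snr_a_db=snr_a, snr_v_db=snr_v, seed=world_ss, n_steps=n_steps,
                mu=0.0, learning_enabled=False, noise_seed=model_noise_ss, sim=sim,
            )
            model_log = run_trial(model_cfg, w_model)
            var_a = model_log.summary["var_a"]
            var_v = model_log.summary["var_v"]
            if np.isfinite(var_a) and np.isfinite(var_v) and var_a > 0 and var_v > 0:
                break
        else:
            raise RuntimeError("could not draw a trial with both cues active")
        rel = normalized_reliabilities(var_a, var_v)
        w_mle = mle_weights(rel)
        mle_cfg = TrialConfig(
            snr_a_db=snr_a, snr_v_db=snr_v, seed=world_ss, n_steps=n_steps,
            mu=0.0, learning_enabled=False, noise_seed=mle_noise_ss, sim=sim,
        )
        mle_log = run_trial(mle_cfg, w_mle)

        row = {
            "trial": k,
            "snr_a_db": snr_a,
            "snr_v_db": snr_v,
            "group": _group_label(snr_a, snr_v),
            "var_a": rel.var_a,
            "var_v": rel.var_v,
            "w_model_a": w_model.w_a,
            "w_model_v": w_model.w_v,
            "w_mle_a": w_mle.w_a,
            "w_mle_v": w_mle.w_v,
        }
        for kind, prefix in (("location", "est"), ("accuracy", "acc")):
            row[f"{prefix}_model"] = trial_location_estimate(
                model_log, "fused-learned", w_model, kind
            ).value
            row[f"{prefix}_mle"] = trial_location_estimate(
                mle_log, "fused-mle", w_mle, kind
            ).value
            row[f"{prefix}_aud"] = trial_location_estimate(
                model_log, "auditory-only", kind=kind
            ).value
            row[f"{prefix}_vis"] = trial_location_estimate(
                model_log, "visual-only", kind=kind
            ).value
        rows.append(row)
    return pd.DataFrame(rows)


def robust_linear_fit(x, y) -> RegressionFit:
    """Iteratively reweighted least squares with Tukey bisquare weights.

    Tuning constant 4.685 with residuals scaled by 1.4826*MAD; residuals
    beyond the bisquare cutoff get exactly zero weight.  ``r2``, ``sse``
    and ``rmse`` are computed on the weighted fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three (x, y) pairs")
    if np.var(x) == 0:
        raise ValueError("degenerate regressor: zero variance in x")
    exog = sm.add_constant(x)
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=50, tol=1e-8, conv="coefs", scale_est="mad")
    p2, p1 = res.params
    w = res.weights
    resid = y - res.fittedvalues
    sse = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    sst = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    dof = max(x.size - 2, 1)
    return RegressionFit(
        p1=float(p1), p2=float(p2), r2=r2, sse=sse,
        rmse=float(np.sqrt(sse / dof)), weights=np.asarray(w),
    )


def welch_t_test(x, y) -> TTestResult:
    """Two-sample unpaired Welch t-test, right tail (mean x > mean y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def variance_comparison(
    estimates: pd.DataFrame, group_col: str = "group", prefix: str = "est"
) -> pd.DataFrame:
    """Across-trial variance of the per-trial estimates, per condition group.

    Columns are the four modes (fused-learned, fused-MLE, auditory-only,
    visual-only); every group needs at least two trials.
    """
    cols = [f"{prefix}_{m}" for m in ("model", "mle", "aud", "vis")]
    out = {}
    for group, sub in estimates.groupby(group_col):
        if len(sub) < 2:
            raise ValueError(f"condition {group!r} has fewer than two trials")
        out[group] = {c: float(np.var(sub[c], ddof=1)) for c in cols}
    return pd.DataFrame(out).T


def mle_comparison_experiment(
    seed: int,
    n_eval_trials: int = 50,
    n_learn_trials: int = 20,
    n_steps: int = 200,
    mu: float = 0.09,
    sim: SimConfig = SimConfig(),
) -> dict:
    """The full learned-model-vs-MLE comparison.

    Learns session-end weights for every SNR condition the randomized
    evaluation can draw (weights carried across ``n_learn_trials`` trials
    per condition), runs ``n_eval_trials`` fixed-weight evaluation trials,
    fits the robust regression of model vs MLE location estimates, and
    performs the four pooled one-tailed Welch t-tests on the accuracy
    estimates (each fused model against each unisensory estimate), plus the
    same tests within each SNR condition group.
    """
    ss = np.random.SeedSequence(seed)
    learn_ss, eval_ss = ss.spawn(2)
    table = learn_weight_table(
        evaluation_conditions(), learn_ss, n_trials=n_learn_trials,
        n_steps=n_steps, mu=mu, sim=sim,
    )
    estimates = run_mle_comparison(
        table, eval_ss, n_trials=n_eval_trials, n_steps=n_steps, sim=sim
    )
    fit = robust_linear_fit(estimates["est_mle"], estimates["est_model"])
    ttests = {
        f"{fused}_vs_{uni}": welch_t_test(
            estimates[f"acc_{fused}"], estimates[f"acc_{uni}"]
        )
        for fused in ("model", "mle")
        for uni in ("aud", "vis")
    }
    ttests_by_group = {
        group: {
            f"{fused}_vs_{uni}": welch_t_test(
                sub[f"acc_{fused}"], sub[f"acc_{uni}"]
            )
            for fused in ("model", "mle")
            for uni in ("aud", "vis")
        }
        for group, sub in estimates.groupby("group")
        if len(sub) >= 2
    }
    return {
        "weight_table": table,
        "estimates": estimates,
        "fit": fit,
        "ttests": ttests,
        "ttests_by_group": ttests_by_group,
        "variances": variance_comparison(estimates),
    }
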