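"""Simulation studies validating the full analysis stack by parameter recovery.

Each function plants known structure with :mod:`serialdep.synthetic`, runs the
corresponding analysis stage, and reports what was recovered: mixed-model
coefficient recovery and model selection, type-I error calibration, decoding
oracle agreement, cluster-level false-positive rates under label shuffling,
activation/reactivation timing recovery, representational-shift sign and
dose-response recovery, cross-correlation lag recovery, and the High/Low-bias
group contrast.  The test suite asserts on these outputs; the reproduction
script reports them.

Problem sizes default to desk-scale versions of the reference paradigm
(documented in the methods note): effect sizes, fold structure, and replicate
counts follow the study design, while nuisance dimensions (channel count,
epoch span, decoding time step) are kept small enough that every study runs
on a single CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from serialdep.behavior import (
    bias_indices,
    compare_models,
    fit_serial_glmm,
    split_bias_groups,
)
from serialdep.permstats import bootstrap_peak_lag, cluster_permutation
from serialdep.rsa import (
    DecodingConfig,
    conditional_decode_timecourse,
    decode_timecourse,
    mahalanobis_to_templates,
)
from serialdep.shift import binary_shift, pairwise_shift_pitch
from serialdep.synthetic import (
    SynthBehaviorConfig,
    SynthNeuralConfig,
    default_features,
    simulate_behavior,
    simulate_epochs,
    with_feature,
)

TRUE_GAMMA = (0.0, 1.2, -0.8, 1.7)

#: Planted activation windows (seconds from noise onset) of the default layout.
FEATURE_WINDOWS = {
    "pitch": (1.08, 1.98),
    "category": (1.15, 1.95),
    "motor": (1.30, 2.00),
}
def _block(n_trials: int) -> int:
    for b in (100, 50, 40, 30, 25, 20, 10, 5):
        if n_trials % b == 0:
            return b
    raise ValueError(f"n_trials={n_trials} must be a multiple of 5")


_FEATURE_COLS = {
    "pitch": ("pitch_level", "prev_pitch", "next_pitch"),
    "category": ("choice", "prev_choice", "next_choice"),
    "motor": ("motor_response", "prev_motor", "next_motor"),
}


def _seed(base: int, *offsets: int) -> int:
    mixed = int(base) % (2**31 - 1)
    for k in offsets:
        mixed = (mixed * 2654435761 + k + 1) % (2**31 - 1)
    return mixed


# ---------------------------------------------------------------------------
# Behavior: recovery and calibration of the mixed models
# ---------------------------------------------------------------------------


def glmm_recovery(
    n_replicates: int = 20,
    n_participants: int = 30,
    n_trials: int = 2000,
    gamma: tuple = TRUE_GAMMA,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate, refit Models 1-4, record the AIC winner and CI coverage."""
    rows = []
    for r in range(n_replicates):
        cfg = SynthBehaviorConfig(
            n_participants=n_participants,
            n_trials=n_trials,
            gamma=gamma,
            seed=_seed(seed, r),
        )
        trials = simulate_behavior(cfg)
        fits = [fit_serial_glmm(trials, m) for m in (1, 2, 3, 4)]
        table = compare_models(fits)
        winner = int(table.index[table["winner"]][0])
        fe = fits[3].fixed_effects
        truth = dict(zip(["intercept", "current_pitch", "prev_pitch", "prev_category"], gamma))
        row = {"replicate": r, "winner": winner}
        for term, value in truth.items():
            row[f"{term}_est"] = fe.loc[term, "estimate"]
            row[f"{term}_covered"] = bool(
                fe.loc[term, "ci_low"] <= value <= fe.loc[term, "ci_high"]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def behavior_type1(
    n_sims: int = 200,
    n_participants: int = 12,
    n_trials: int = 150,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Wald-test rejection rates for the history terms when both are truly 0."""
    Sigma = np.diag([0.09, 0.04, 0.0, 0.0])
    rows = []
    for r in range(n_sims):
        cfg = SynthBehaviorConfig(
            n_participants=n_participants,
            n_trials=n_trials,
            block_size=min(50, n_trials),
            gamma=(0.0, 1.2, 0.0, 0.0),
            Sigma=Sigma,
            seed=_seed(seed, r, 7),
        )
        fit = fit_serial_glmm(simulate_behavior(cfg), 4, max_outer=50)
        rows.append(
            {
                "sim": r,
                "p_prev_pitch": fit.fixed_effects.loc["prev_pitch", "p"],
                "p_prev_category": fit.fixed_effects.loc["prev_category", "p"],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# Decoding: oracle equivalence and null calibration
# ---------------------------------------------------------------------------


def decoding_oracle_error(seed: int = 0) -> float:
    """Max |difference| between the shrinkage path at gamma=0 and an
    explicit-inverse Mahalanobis computation on a 40-trial, 6-feature toy."""
    rng = np.random.default_rng(seed)
    train = rng.normal(size=(40, 6))
    labels = np.repeat([0, 1, 2, 3], 10)
    train += 1.5 * rng.normal(size=(4, 6))[labels]
    test = rng.normal(size=(15, 6))
    ours = mahalanobis_to_templates(train, labels, test, [0, 1, 2, 3], shrinkage=0.0)
    mus = np.stack([train[labels == c].mean(axis=0) for c in range(4)])
    resid = train - mus[labels]
    icov = np.linalg.inv(resid.T @ resid / len(train))
    worst = 0.0
    for i in range(len(test)):
        for c in range(4):
            diff = test[i] - mus[c]
            worst = max(worst, abs(ours[i, c] - np.sqrt(diff @ icov @ diff)))
    return worst


def _null_participant_scores(
    n_participants: int,
    n_trials: int,
    n_channels: int,
    time_step: int,
    seed: int,
):
    """Label-shuffled decoding timecourses, one row per simulated participant."""
    scores = []
    times = None
    for i in range(n_participants):
        bcfg = SynthBehaviorConfig(
            n_participants=1, n_trials=n_trials, block_size=_block(n_trials), seed=_seed(seed, i, 1)
        )
        trials = simulate_behavior(bcfg)
        ncfg = SynthNeuralConfig(
            n_channels=n_channels,
            t_start=0.25,
            t_stop=2.25,
            features=default_features(),
            seed=_seed(seed, i, 2),
        )
        epochs = simulate_epochs(trials, ncfg)
        rng = np.random.default_rng(_seed(seed, i, 3))
        labels = rng.permutation(trials["choice"].to_numpy())
        cfg = DecodingConfig(
            window_samples=1, n_folds=8, n_reps=1, time_step=time_step,
            seed=_seed(seed, i, 4),
        )
        tc = decode_timecourse(epochs, labels, cfg)
        scores.append(tc.score)
        times = tc.times
    return np.asarray(scores), times


def decoding_null_fwer(
    n_runs: int = 200,
    n_participants: int = 20,
    n_trials: int = 200,
    n_channels: int = 16,
    time_step: int = 20,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Cluster-level family-wise error rate with shuffled labels."""
    hits = 0
    for run in range(n_runs):
        scores, times = _null_participant_scores(
            n_participants, n_trials, n_channels, time_step, _seed(seed, run, 11)
        )
        res = cluster_permutation(
            scores, n_perm=n_perm, tail="greater", seed=_seed(seed, run, 12), times=times
        )
        hits += bool(res.significant(alpha))
    return {"fwer": hits / n_runs, "hits": hits, "n_runs": n_runs}


# ---------------------------------------------------------------------------
# Decoding: planted-window recovery and reactivation specificity
# ---------------------------------------------------------------------------


def _participant_set(
    n_participants: int,
    n_trials: int,
    n_channels: int,
    seed: int,
    reactivation_gain: float = 0.0,
    feature_overrides: dict | None = None,
    t_start: float = 0.7,
    t_stop: float = 2.25,
    gamma: tuple | None = None,
):
    """Simulate per-participant (trials, epochs) with the standard layout."""
    out = []
    for i in range(n_participants):
        kw = {} if gamma is None else {"gamma": gamma}
        bcfg = SynthBehaviorConfig(
            n_participants=1, n_trials=n_trials, block_size=_block(n_trials),
            seed=_seed(seed, i, 21), **kw,
        )
        trials = simulate_behavior(bcfg)
        feats = default_features(reactivation_gain=reactivation_gain)
        ncfg = SynthNeuralConfig(
            n_channels=n_channels,
            t_start=t_start,
            t_stop=t_stop,
            features=feats,
            seed=_seed(seed, i, 22),
        )
        if feature_overrides:
            for name, kw in feature_overrides.items():
                ncfg = with_feature(ncfg, name, **kw)
        out.append((trials, simulate_epochs(trials, ncfg)))
    return out


def _cluster_spans(scores: np.ndarray, times: np.ndarray, tail: str, n_perm: int, seed: int, alpha=0.05):
    res = cluster_permutation(scores, n_perm=n_perm, tail=tail, seed=seed, times=times)
    return [(c["start_s"], c["end_s"]) for c in res.significant(alpha)], res


def decoding_recovery(
    n_runs: int = 20,
    n_participants: int = 8,
    n_trials: int = 200,
    n_channels: int = 16,
    n_perm: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Current-feature decoding: detection and onset accuracy per feature."""
    rows = []
    for run in range(n_runs):
        # features are decoupled here (no stimulus-choice or history coupling)
        # so that each feature's information onset is exactly its envelope
        # onset; feature entanglement is exercised by the conditional-decoding
        # and reactivation studies instead
        data = _participant_set(
            n_participants, n_trials, n_channels, _seed(seed, run, 31),
            gamma=(0.0, 0.0, 0.0, 0.0),
        )
        for feature, (w0, w1) in FEATURE_WINDOWS.items():
            col = _FEATURE_COLS[feature][0]
            scores, times = [], None
            for i, (trials, epochs) in enumerate(data):
                cfg = DecodingConfig(
                    n_folds=8, n_reps=1, time_step=1, seed=_seed(seed, run, 32, i)
                )
                tc = decode_timecourse(epochs, trials[col].to_numpy(), cfg)
                scores.append(tc.score)
                times = tc.times
            spans, _ = _cluster_spans(
                np.asarray(scores), times, "greater", n_perm, _seed(seed, run, 33)
            )
            overlapping = [s for s in spans if s[0] < w1 and s[1] > w0]
            onset = min((s[0] for s in overlapping), default=np.nan)
            rows.append(
                {
                    "run": run,
                    "feature": feature,
                    "detected": bool(overlapping),
                    "onset_s": onset,
                    "onset_error_s": onset - w0 if overlapping else np.nan,
                    "earliest_cluster_s": min((s[0] for s in spans), default=np.nan),
                }
            )
    return pd.DataFrame(rows)


def reactivation_specificity(
    n_participants: int = 8,
    n_trials: int = 300,
    n_channels: int = 16,
    reactivation_gain: float = 0.6,
    time_step: int = 2,
    n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Conditional previous/future-feature decoding with tone/cue-locked gains.

    Previous pitch and category carry reactivation only inside their
    tone-locked windows; previous motor only inside its cue-locked window.
    Future (next-trial) labels carry no planted signal at all.
    """
    data = _participant_set(
        n_participants, n_trials, n_channels, _seed(seed, 41),
        reactivation_gain=reactivation_gain,
    )
    results = {}
    for feature in ("pitch", "category", "motor"):
        cur_col, prev_col, next_col = _FEATURE_COLS[feature]
        for target_name, target_col in (("prev", prev_col), ("next", next_col)):
            if target_name == "next" and feature != "pitch":
                continue  # one future-control feature suffices
            scores, times = [], None
            for i, (trials, epochs) in enumerate(data):
                ok = trials[target_col].notna().to_numpy()
                cfg = DecodingConfig(
                    n_folds=4, n_reps=1, time_step=time_step,
                    seed=_seed(seed, 42, i),
                )
                tc = conditional_decode_timecourse(
                    epochs.subset(ok),
                    trials.loc[ok, target_col].to_numpy(),
                    trials.loc[ok, cur_col].to_numpy(),
                    cfg,
                )
                scores.append(tc.score)
                times = tc.times
            spans, _ = _cluster_spans(
                np.asarray(scores), times, "greater", n_perm, _seed(seed, 43)
            )
            results[f"{feature}_{target_name}"] = {"clusters": spans, "times": times}
    return results


# ---------------------------------------------------------------------------
# Shift recovery
# ---------------------------------------------------------------------------

SHIFT_LAMBDAS = {"pitch": -0.3, "category": +0.3, "motor": -0.3}


def _shift_scores(
    data, feature: str, time_step: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    scores, times = [], None
    cur_col, prev_col, _ = _FEATURE_COLS[feature]
    for i, (trials, epochs) in enumerate(data):
        cfg = DecodingConfig(
            n_folds=4, n_reps=1, time_step=time_step, seed=_seed(seed, i, 51)
        )
        if feature == "pitch":
            st = pairwise_shift_pitch(
                epochs, trials[cur_col].to_numpy(), trials[prev_col].to_numpy(), cfg
            )
        else:
            st = binary_shift(
                epochs, trials[cur_col].to_numpy(), trials[prev_col].to_numpy(), cfg,
                feature=feature,
            )
        scores.append(st.shift)
        times = st.times
    return np.asarray(scores), times


def shift_recovery(
    n_runs: int = 20,
    n_participants: int = 6,
    n_trials: int = 240,
    n_channels: int = 12,
    lambdas: dict = SHIFT_LAMBDAS,
    time_step: int = 3,
    n_perm: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Sign-pattern recovery of planted shifts (or the null when lambda=0)."""
    rows = []
    for run in range(n_runs):
        overrides = {f: {"shift_lambda": lam} for f, lam in lambdas.items()}
        data = _participant_set(
            n_participants, n_trials, n_channels, _seed(seed, run, 61),
            feature_overrides=overrides,
        )
        for feature, lam in lambdas.items():
            scores, times = _shift_scores(data, feature, time_step, _seed(seed, run, 62))
            res = cluster_permutation(
                scores, n_perm=n_perm, tail="two-sided",
                seed=_seed(seed, run, 63), times=times,
            )
            sig = res.significant(0.05)
            pos = [c for c in sig if c["mass"] > 0]
            neg = [c for c in sig if c["mass"] < 0]
            w0, w1 = FEATURE_WINDOWS[feature]
            in_window = [
                c for c in sig if c["start_s"] < w1 + 0.1 and c["end_s"] > w0 - 0.1
            ]
            rows.append(
                {
                    "run": run,
                    "feature": feature,
                    "lambda": lam,
                    "n_pos": len(pos),
                    "n_neg": len(neg),
                    "any_cluster": bool(sig),
                    "sign_correct": bool(
                        in_window
                        and all(np.sign(c["mass"]) == np.sign(lam) for c in in_window)
                        and any(np.sign(c["mass"]) == np.sign(lam) for c in in_window)
                    )
                    if lam != 0
                    else not sig,
                    "mean_shift_in_window": float(
                        scores[:, (times >= w0) & (times <= w1)].mean()
                    ),
                }
            )
    return pd.DataFrame(rows)


def shift_dose_response(
    lams: tuple = (0.1, 0.2, 0.3),
    n_participants: int = 6,
    n_trials: int = 240,
    n_channels: int = 12,
    time_step: int = 3,
    seed: int = 0,
) -> dict:
    """Mean |Shift_dist| inside the pitch window as a function of |lambda|."""
    out = {}
    w0, w1 = FEATURE_WINDOWS["pitch"]
    for lam in lams:
        data = _participant_set(
            n_participants, n_trials, n_channels, _seed(seed, 71),
            feature_overrides={"pitch": {"shift_lambda": -lam}},
        )
        scores, times = _shift_scores(data, "pitch", time_step, _seed(seed, 72))
        out[lam] = float(np.abs(scores[:, (times >= w0) & (times <= w1)].mean()))
    return out


# ---------------------------------------------------------------------------
# Cross-correlation lag recovery
# ---------------------------------------------------------------------------


def xcorr_lag_recovery(
    n_participants: int = 6,
    n_trials: int = 200,
    n_channels: int = 16,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Recover the designed 250-ms tone-to-cue lag and a zero-lag control.

    Pitch and motor envelopes share one shape but lock to events 250 ms
    apart; pitch and category share both shape and event.
    """
    shape = {"onset": 0.08, "duration": 0.9, "rise": 0.05, "fall": 0.15}
    overrides = {f: dict(shape) for f in ("pitch", "category", "motor")}
    data = _participant_set(
        n_participants, n_trials, n_channels, _seed(seed, 81),
        feature_overrides=overrides,
    )
    curves = {}
    for feature in ("pitch", "category", "motor"):
        col = _FEATURE_COLS[feature][0]
        scores, times = [], None
        for i, (trials, epochs) in enumerate(data):
            cfg = DecodingConfig(n_folds=8, n_reps=1, time_step=1, seed=_seed(seed, 82, i))
            tc = decode_timecourse(epochs, trials[col].to_numpy(), cfg)
            scores.append(tc.score)
            times = tc.times
        curves[feature] = np.asarray(scores)
    sfreq = 1.0 / float(np.diff(times)[0])

    offset = bootstrap_peak_lag(
        curves["pitch"], curves["motor"], sfreq, 0.5, n_boot=n_boot, seed=_seed(seed, 83)
    )
    zero = bootstrap_peak_lag(
        curves["pitch"], curves["category"], sfreq, 0.5, n_boot=n_boot, seed=_seed(seed, 84)
    )
    return {
        "offset_peak_lag_s": offset["peak_lag_s"],
        "offset_ci_s": (offset["ci_low_s"], offset["ci_high_s"]),
        "zero_peak_lag_s": zero["peak_lag_s"],
        "zero_ci_s": (zero["ci_low_s"], zero["ci_high_s"]),
    }


# ---------------------------------------------------------------------------
# High/Low-bias group contrast
# ---------------------------------------------------------------------------


def group_split_contrast(
    n_participants: int = 16,
    n_trials: int = 300,
    n_channels: int = 12,
    lam_high: float = 0.35,
    lam_low: float = 0.0,
    gamma3_high: float = 2.2,
    gamma3_low: float = 0.3,
    time_step: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Participants with strong behavioral category bias carry a real neural
    shift; weak-bias participants carry none.  Median-splitting on fitted
    behavioral bias should isolate the shift in the High-bias group."""
    half = n_participants // 2
    planted_high = {}
    frames, shifts, times = [], [], None
    for i in range(n_participants):
        is_high = i < half
        planted = lam_high if is_high else lam_low
        g3 = gamma3_high if is_high else gamma3_low
        bcfg = SynthBehaviorConfig(
            n_participants=1, n_trials=n_trials, block_size=_block(n_trials),
            gamma=(0.0, 1.2, -0.8, g3), Sigma=np.diag([0.04, 0.02, 0.01, 0.04]),
            seed=_seed(seed, i, 91),
        )
        trials = simulate_behavior(bcfg)
        pid = f"S{i:02d}"
        trials["participant"] = pid
        planted_high[pid] = is_high
        ncfg = SynthNeuralConfig(
            n_channels=n_channels, t_start=0.7, t_stop=2.25,
            seed=_seed(seed, i, 92),
        )
        ncfg = with_feature(ncfg, "category", shift_lambda=planted)
        epochs = simulate_epochs(trials, ncfg)
        cfg = DecodingConfig(n_folds=4, n_reps=1, time_step=time_step, seed=_seed(seed, i, 93))
        st = binary_shift(
            epochs, trials["choice"].to_numpy(), trials["prev_choice"].to_numpy(), cfg
        )
        shifts.append(st.shift)
        times = st.times
        frames.append(trials)

    all_trials = pd.concat(frames, ignore_index=True)
    idx = bias_indices(all_trials)
    groups = split_bias_groups(idx, "category")
    shifts = np.asarray(shifts)
    order = list(idx.table.index)
    shift_by_pid = {pid: shifts[i] for i, pid in enumerate(sorted(planted_high))}
    # participants were named in order, so sorted ids match simulation order
    high_scores = np.stack([shift_by_pid[p] for p in order if groups[p] == "High"])
    low_scores = np.stack([shift_by_pid[p] for p in order if groups[p] == "Low"])

    res_high = cluster_permutation(
        high_scores, n_perm=n_perm, tail="greater", seed=_seed(seed, 94), times=times
    )
    res_low = cluster_permutation(
        low_scores, n_perm=n_perm, tail="greater", seed=_seed(seed, 95), times=times
    )
    match = np.mean([groups[p] == ("High" if planted_high[p] else "Low") for p in order])
    return {
        "high_significant": bool(res_high.significant(0.05)),
        "low_significant": bool(res_low.significant(0.05)),
        "split_matches_planted": float(match),
        "high_clusters": [(c["start_s"], c["end_s"]) for c in res_high.significant(0.05)],
    }
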