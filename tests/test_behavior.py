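"""Behavioral analyses: mixed models, aggregate curves, bias indices."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from serialdep.behavior import (
    BiasIndices,
    aggregate_choice_curves,
    bias_indices,
    category_bias_by_distance,
    compare_models,
    fit_pointwise_logistic,
    fit_serial_glmm,
    motor_switch_bias,
    split_bias_groups,
    _design,
)
from serialdep.glmm import logistic_irls
from serialdep.synthetic import SynthBehaviorConfig, simulate_behavior

from conftest import make_trials


class TestSerialGLMM:
    def test_aic_identity(self, behavior_small):
        _, trials = behavior_small
        fit = fit_serial_glmm(trials, 2)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-9)
        assert (fit.fixed_effects["ci_low"] <= fit.fixed_effects["ci_high"]).all()

    def test_null_intercept_small(self):
        cfg = SynthBehaviorConfig(
            n_participants=4, n_trials=400, block_size=50,
            gamma=(0, 1.0, 0, 0), Sigma=np.zeros((4, 4)), seed=11,
        )
        fit = fit_serial_glmm(simulate_behavior(cfg), 1)
        assert abs(fit.coef("intercept")) < 0.1
        assert abs(fit.fixed_effects.loc["intercept", "z"]) < 2.5

    def test_recovers_history_signs(self, behavior_small):
        _, trials = behavior_small
        fit = fit_serial_glmm(trials, 4)
        assert fit.coef("prev_pitch") < -0.3
        assert fit.coef("prev_category") > 0.8
        assert fit.coef("current_pitch") > 0.8

    def test_sigma_zero_limit_matches_per_participant_glms(self):
        """With no true heterogeneity the mixed fit tracks the pooled GLM."""
        cfg = SynthBehaviorConfig(
            n_participants=5, n_trials=400, block_size=50,
            Sigma=np.zeros((4, 4)), seed=12,
        )
        trials = simulate_behavior(cfg)
        fit = fit_serial_glmm(trials, 4)
        X, y, groups, names = _design(trials, 4)
        per = np.stack(
            [logistic_irls(X[groups == g], y[groups == g])[0] for g in np.unique(groups)]
        )
        assert np.allclose(fit.result.gamma, per.mean(axis=0), atol=0.12)

    def test_matches_lme4_reference(self):
        """Cross-check the Laplace fitter against lme4::glmer on one dataset."""
        cfg = SynthBehaviorConfig(n_participants=8, n_trials=250, block_size=50, seed=21)
        trials = simulate_behavior(cfg)
        fit = fit_serial_glmm(trials, 4)
        X, y, groups, names = _design(trials, 4)
        df = pd.DataFrame(X, columns=names).assign(y=y, g=groups)
        import tempfile, os

        with tempfile.TemporaryDirectory() as td:
            csv = os.path.join(td, "d.csv")
            df.to_csv(csv, index=False)
            script = textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv('{csv}')
                m <- glmer(y ~ current_pitch + prev_pitch + prev_category +
                           (1 + current_pitch + prev_pitch + prev_category | g),
                           data = d, family = binomial,
                           control = glmerControl(optimizer = 'bobyqa',
                                                  calc.derivs = FALSE))
                cat(fixef(m), as.numeric(logLik(m)), sep='\\n')
                """
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=600
            )
            vals = [float(v) for v in out.stdout.strip().splitlines()[-5:]]
        ref_fix, ref_ll = np.array(vals[:4]), vals[4]
        assert np.allclose(fit.result.gamma, ref_fix, atol=0.02)
        assert fit.loglik == pytest.approx(ref_ll, abs=1.0)


class TestModelComparison:
    def test_identical_model_delta_zero(self, behavior_small):
        _, trials = behavior_small
        f = fit_serial_glmm(trials, 1)
        table = compare_models([f, f])
        assert table["delta_aic"].abs().max() == 0.0

    def test_mismatched_nobs_refused(self, behavior_small):
        _, trials = behavior_small
        f1 = fit_serial_glmm(trials, 1)
        f2 = fit_serial_glmm(trials.iloc[: len(trials) // 2], 2)
        with pytest.raises(ValueError, match="n_obs"):
            compare_models([f1, f2])

    def test_model4_wins_with_history_effects(self, behavior_small):
        _, trials = behavior_small
        fits = [fit_serial_glmm(trials, m) for m in (1, 2, 3, 4)]
        table = compare_models(fits)
        assert table.loc[4, "winner"]
        assert table.loc[4, "delta_aic"] < -50


class TestAggregateCurves:
    def test_all_high_choices(self):
        trials = make_trials([1, 2, 3, 4, 5, 1], choices=[1] * 6)
        table = aggregate_choice_curves(trials, "prev_pitch")
        filled = table[~table["empty"]]
        assert (filled["p_high"] == 1.0).all()

    def test_hand_tally(self):
        trials = make_trials(
            [3, 3, 3, 3, 2, 3], choices=[1, 0, 1, 1, 0, 1]
        )
        table = aggregate_choice_curves(trials, "prev_choice").set_index(
            ["prev_choice", "pitch_level"]
        )
        # prev_choice=1 & pitch 3: trials 1 (choice 0) and 3 (choice 1)
        assert table.loc[(1.0, 3), "n"] == 2
        assert table.loc[(1.0, 3), "p_high"] == pytest.approx(1 / 2)
        # prev_choice=0 & pitch 3: trials 2 and 5, both "high"
        assert table.loc[(0.0, 3), "n"] == 2
        assert table.loc[(0.0, 3), "p_high"] == pytest.approx(1.0)

    def test_attractive_category_bias_separates_curves(self, behavior_small):
        _, trials = behavior_small
        table = aggregate_choice_curves(trials, "prev_choice")
        wide = table.pivot(index="pitch_level", columns="prev_choice", values="p_high")
        # attraction: percent-high larger after a "high" choice at every pitch
        assert (wide[1.0] > wide[0.0]).sum() >= 4


class TestPointwiseLogistic:
    def test_symmetric_percents_invert_to_levels(self):
        levels = np.array([1, 2, 3, 4, 5])
        p = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        totals = np.full(5, 2000)
        fit = fit_pointwise_logistic(levels, p * totals, totals)
        assert fit.predict([3])[0] == pytest.approx(0.5, abs=0.02)
        # a single logistic cannot pass exactly through all five points;
        # the ML compromise lands within a quarter level everywhere
        assert np.allclose(fit.inverse(p), levels, atol=0.25)

    def test_flat_data_zero_slope(self):
        fit = fit_pointwise_logistic([1, 2, 3], [50, 50, 50], [100, 100, 100])
        assert abs(fit.slope) < 1e-6

    def test_recovers_planted_coefficients(self):
        rng = np.random.default_rng(0)
        levels = np.arange(1, 6, dtype=float)
        intercept, slope = -3.0, 1.0
        p = 1 / (1 + np.exp(-(intercept + slope * levels)))
        totals = np.full(5, 10000)
        succ = rng.binomial(totals, p)
        fit = fit_pointwise_logistic(levels, succ, totals)
        assert fit.intercept == pytest.approx(intercept, abs=0.1)
        assert fit.slope == pytest.approx(slope, abs=0.05)

    def test_separation_flagged(self):
        fit = fit_pointwise_logistic([1, 2, 4, 5], [0, 0, 30, 30], [30, 30, 30, 30])
        assert fit.separation_flagged


class TestCategoryBiasByDistance:
    def test_toy_hand_arithmetic(self):
        # current pitch 3 preceded by pitch 3; effect at distance 0 only
        trials = make_trials(
            [3, 3, 3, 3, 3, 3, 3],
            choices=[1, 1, 0, 0, 1, 0, 1],
        )
        res = category_bias_by_distance(trials, n_perm=50, n_boot=50, seed=0)
        rows = trials.dropna(subset=["prev_choice"])
        hi = rows[rows["prev_choice"] == 1]["choice"].mean()
        lo = rows[rows["prev_choice"] == 0]["choice"].mean()
        assert res.loc[0, "effect"] == pytest.approx(hi - lo)
        assert np.isnan(res.loc[4, "effect"])

    def test_null_effects_near_zero(self):
        cfg = SynthBehaviorConfig(
            n_participants=4, n_trials=500, block_size=50,
            gamma=(0, 1.2, 0, 0), Sigma=np.zeros((4, 4)), seed=13,
        )
        trials = simulate_behavior(cfg)
        res = category_bias_by_distance(trials, n_perm=200, n_boot=200, seed=1)
        assert np.nanmax(np.abs(res["effect"])) < 0.12
        assert (res["p"].dropna() > 0.01).all()

    def test_attraction_decreases_with_distance(self, behavior_small):
        _, trials = behavior_small
        res = category_bias_by_distance(trials, n_perm=200, n_boot=200, seed=2)
        eff = res["effect"].to_numpy()
        assert eff[0] > eff[2] > eff[4] - 0.05
        assert eff[0] > 0.15


class TestMotorBias:
    def test_alternating_responses(self):
        trials = make_trials([3] * 6, motors=[0, 1, 0, 1, 0, 1])
        per, _ = motor_switch_bias(trials)
        assert per["switch_rate"].iloc[0] == 1.0
        assert per["switch_rate"].iloc[0] + per["stay_rate"].iloc[0] == 1.0

    def test_fair_coin_null_calibrated(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(40):
            motors = rng.integers(0, 2, 200).tolist()
            trials = make_trials([3] * 400, participants=["A"] * 200 + ["B"] * 200,
                                 motors=motors + rng.integers(0, 2, 200).tolist())
            per, test = motor_switch_bias(trials)
            ps.append(test["p"])
        assert np.mean(np.array(ps) < 0.05) < 0.25  # near-nominal false positives

    def test_planted_switch_bias_detected(self):
        cfg = SynthBehaviorConfig(n_participants=10, n_trials=1000, block_size=100,
                                  switch_prob=0.54, seed=14)
        per, test = motor_switch_bias(simulate_behavior(cfg))
        assert (per["switch_rate"] > 0.5).all()
        assert test["t"] > 0 and test["p"] < 0.01


class TestBiasSplit:
    def test_equal_groups_and_tiebreak(self):
        tab = pd.DataFrame(
            {"pitch_bias": [0.0] * 6, "category_bias": [0.0] * 6, "motor_bias": [0.0] * 6},
            index=pd.Index([f"P{i}" for i in range(6)], name="participant"),
        )
        labels = split_bias_groups(BiasIndices(tab, "blup"), "pitch")
        assert (labels == "High").sum() == 3
        labels2 = split_bias_groups(BiasIndices(tab, "blup"), "pitch")
        assert labels.equals(labels2)

    def test_bimodal_population_split_matches_truth(self):
        rng = np.random.default_rng(4)
        strong = rng.normal(-1.5, 0.1, 8)
        weak = rng.normal(-0.1, 0.1, 8)
        tab = pd.DataFrame(
            {
                "pitch_bias": np.r_[strong, weak],
                "category_bias": 0.0,
                "motor_bias": 0.0,
            },
            index=pd.Index([f"P{i:02d}" for i in range(16)], name="participant"),
        )
        labels = split_bias_groups(BiasIndices(tab, "blup"), "pitch")
        assert (labels.iloc[:8] == "High").all()
        assert (labels.iloc[8:] == "Low").all()

    def test_blup_indices_track_truth_direction(self, behavior_small):
        _, trials = behavior_small
        idx = bias_indices(trials)
        assert idx.table["pitch_bias"].mean() < 0
        assert idx.table["category_bias"].mean() > 0
        assert idx.table["motor_bias"].abs().max() <= 1.0
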