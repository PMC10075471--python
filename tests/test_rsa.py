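"""Decoding machinery: patterns, shrinkage covariance, CV distances, scores."""

import numpy as np
import pytest
from sklearn.covariance import LedoitWolf

from serialdep.io import EpochSet
from serialdep.rsa import (
    DecodingConfig,
    conditional_decode_timecourse,
    crossval_distances,
    decode_timecourse,
    distance_regression_score,
    mahalanobis_to_templates,
    regress_out_condition,
    shrinkage_covariance,
    smooth_for_display,
    spatiotemporal_patterns,
)


def make_epochs(data, sfreq=100.0, t0=0.0):
    n, c, s = data.shape
    keys = np.array([["P01", i] for i in range(n)], dtype=object)
    return EpochSet(
        data=data,
        sampling_rate=sfreq,
        times=t0 + np.arange(s) / sfreq,
        channel_labels=[f"CH{i}" for i in range(c)],
        trial_keys=keys,
    )


class TestPatterns:
    def test_window_two_doubles_features(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.normal(size=(5, 64, 10)))
        pat = spatiotemporal_patterns(ep, 4, 2)
        assert pat.shape == (5, 128)

    def test_window_one_is_raw_channels(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.normal(size=(4, 6, 8)))
        assert np.array_equal(spatiotemporal_patterns(ep, 3, 1), ep.data[:, :, 3])

    def test_sample_major_layout(self):
        data = np.arange(2 * 3 * 4, dtype=float).reshape(2, 3, 4)
        ep = make_epochs(data)
        pat = spatiotemporal_patterns(ep, 2, 2)
        # earliest sample's channels first, then current sample's channels
        expected = np.concatenate([data[:, :, 1], data[:, :, 2]], axis=1)
        assert np.array_equal(pat, expected)

    def test_out_of_range_rejected(self):
        ep = make_epochs(np.zeros((2, 3, 5)))
        with pytest.raises(IndexError):
            spatiotemporal_patterns(ep, 0, 2)


class TestShrinkageCovariance:
    def test_matches_sklearn_ledoit_wolf(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 12)) @ rng.normal(size=(12, 12))
        ours = shrinkage_covariance(X)
        ref = LedoitWolf().fit(X).covariance_
        assert np.allclose(ours, ref, atol=1e-10)

    def test_large_n_approaches_sample_covariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5000, 8))
        ours = shrinkage_covariance(X)
        samp = np.cov(X.T, bias=True)
        rel = np.linalg.norm(ours - samp) / np.linalg.norm(samp)
        assert rel < 0.05

    def test_degenerate_input_stays_spd(self):
        X = np.tile([1.0, 2.0, 3.0], (6, 1))  # identical rows
        cov = shrinkage_covariance(X)
        assert np.linalg.eigvalsh(cov).min() >= 0  # scaled identity with zero scale
        X2 = np.c_[np.random.default_rng(4).normal(size=(5, 1)), np.ones((5, 1))]
        assert np.linalg.eigvalsh(shrinkage_covariance(X2)).min() > 0

    def test_p_larger_than_n_spd(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 20))
        assert np.linalg.eigvalsh(shrinkage_covariance(X)).min() > 0


class TestCrossvalDistances:
    def test_identity_covariance_equals_euclidean_oracle(self):
        """Shrinkage path with gamma=0 vs explicit-inverse brute force."""
        rng = np.random.default_rng(6)
        train = rng.normal(size=(40, 6))
        labels = np.repeat([0, 1], 20)
        train[labels == 1] += 2.0
        test = rng.normal(size=(10, 6))
        d = mahalanobis_to_templates(train, labels, test, [0, 1], shrinkage=0.0)
        # brute force: explicit covariance inverse
        mus = np.stack([train[labels == c].mean(axis=0) for c in (0, 1)])
        resid = train - mus[labels]
        cov = resid.T @ resid / len(train)
        icov = np.linalg.inv(cov)
        for i in range(10):
            for c in (0, 1):
                diff = test[i] - mus[c]
                ref = np.sqrt(diff @ icov @ diff)
                assert d[i, c] == pytest.approx(ref, abs=1e-8)

    def test_separated_clouds_classified(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        labels = np.repeat([0, 1, 2], 20)
        X += 8.0 * np.eye(5)[labels][:, :5]
        cfg = DecodingConfig(n_folds=4, n_reps=2, seed=0)
        d, conds = crossval_distances(X, labels, cfg)
        assert np.array_equal(np.asarray(conds)[d.argmin(axis=1)], labels)

    def test_label_shuffle_zero_score(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 6))
        labels = rng.permutation(np.repeat([0, 1], 40))
        cfg = DecodingConfig(n_folds=4, n_reps=5, seed=1)
        d, conds = crossval_distances(X, labels, cfg)
        score = distance_regression_score(d, labels, conds)
        assert abs(score) < 0.1

    def test_too_few_trials_per_condition_named(self):
        X = np.random.default_rng(9).normal(size=(10, 4))
        labels = np.array([0] * 7 + [1] * 3)
        with pytest.raises(ValueError, match="1"):
            crossval_distances(X, labels, DecodingConfig(n_folds=4, n_reps=1))


class TestScore:
    def test_two_point_slope(self):
        d = np.tile([1.0, 3.0], (5, 1))
        labels = np.zeros(5, dtype=int)
        assert distance_regression_score(d, labels, np.array([0, 1])) == pytest.approx(2.0)

    def test_label_independent_distances_zero(self):
        d = np.tile([2.0, 2.0, 2.0], (9, 1))
        labels = np.repeat([0, 1, 2], 3)
        assert distance_regression_score(d, labels, np.array([0, 1, 2])) == 0.0

    def test_five_condition_hand_ols(self):
        # one trial, own distance 1, others 2,3,4,5: slope = mean(2,3,4,5) - 1
        d = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        labels = np.array([0])
        score = distance_regression_score(d, labels, np.arange(5))
        assert score == pytest.approx(np.mean([2, 3, 4, 5]) - 1.0)


class TestRegressOut:
    def test_pure_confound_variance_removed(self):
        rng = np.random.default_rng(10)
        conf = np.repeat([0, 1], 20)
        template = rng.normal(size=6)
        X = np.outer(conf, template)
        resid = regress_out_condition(X, conf)
        means = [resid[conf == v].mean(axis=0) for v in (0, 1)]
        assert np.allclose(means[0], means[1], atol=1e-12)

    def test_balanced_confound_means_equalized(self):
        rng = np.random.default_rng(11)
        conf = np.tile([0, 1], 15)
        X = rng.normal(size=(30, 4)) + np.outer(conf, rng.normal(size=4))
        resid = regress_out_condition(X, conf)
        assert np.allclose(
            resid[conf == 0].mean(axis=0), resid[conf == 1].mean(axis=0), atol=1e-12
        )
        assert np.allclose(resid.mean(axis=0), X.mean(axis=0), atol=1e-12)

    def test_single_level_warns_identity(self):
        X = np.random.default_rng(12).normal(size=(6, 3))
        with pytest.warns(UserWarning, match="single level"):
            out = regress_out_condition(X, np.zeros(6))
        assert np.array_equal(out, X)


class TestTimecourses:
    def test_zero_noise_score_confined_to_envelope(self, epochs_small):
        from serialdep.synthetic import SynthNeuralConfig, simulate_epochs

        trials, _, _ = epochs_small
        cfg = SynthNeuralConfig(
            n_channels=12, t_start=0.7, t_stop=2.1, noise_amplitude=1e-6, seed=0
        )
        ep = simulate_epochs(trials, cfg)
        dcfg = DecodingConfig(n_folds=4, n_reps=1, time_step=4, seed=0)
        tc = decode_timecourse(ep, trials["pitch_level"].to_numpy(), dcfg)
        active = (tc.times > 1.15) & (tc.times < 1.9)
        silent = tc.times < 1.05
        # Mahalanobis whitening rescales the residual noise to unit size, so
        # the silent-period scores are zero-mean jitter, tiny relative to the
        # template-driven scores inside the envelope
        assert tc.score[active].min() > 1.0
        assert np.abs(tc.score[silent]).max() < 0.05 * tc.score[active].min()

    def test_window_start_trimmed(self):
        ep = make_epochs(np.random.default_rng(13).normal(size=(24, 4, 10)))
        labels = np.repeat([0, 1], 12)
        cfg = DecodingConfig(window_samples=3, n_folds=3, n_reps=1, seed=0)
        tc = decode_timecourse(ep, labels, cfg)
        assert len(tc.times) == 8
        assert tc.times[0] == pytest.approx(ep.times[2])

    def test_conditional_requires_usable_strata(self):
        ep = make_epochs(np.random.default_rng(14).normal(size=(40, 4, 6)))
        labels = np.repeat([0, 1], 20)
        with pytest.raises(ValueError, match="strata"):
            conditional_decode_timecourse(
                ep, labels, labels, DecodingConfig(n_folds=4, n_reps=1)
            )

    def test_rep_averaging_reduces_variance(self):
        rng = np.random.default_rng(15)
        data = rng.normal(size=(48, 6, 3))
        labels = np.repeat([0, 1], 24)
        data[labels == 1, :2, :] += 0.8
        ep = make_epochs(data)

        def score_sd(n_reps, n=12):
            scores = [
                decode_timecourse(
                    ep, labels, DecodingConfig(n_folds=4, n_reps=n_reps, seed=s),
                ).score[1]
                for s in range(n)
            ]
            return np.std(scores)

        assert score_sd(8) < score_sd(1)


class TestSmoothing:
    def test_constant_preserved(self):
        x = np.full(50, 3.7)
        assert np.allclose(smooth_for_display(x, 100.0), x, atol=1e-12)

    def test_impulse_becomes_gaussian(self):
        x = np.zeros(101)
        x[50] = 1.0
        sm = smooth_for_display(x, 100.0, window_ms=150)
        assert sm[50] == sm.max()
        assert np.all(np.diff(sm[43:51]) > 0)  # monotone rise on the kernel support
        assert sm.sum() == pytest.approx(1.0, abs=1e-6)

    def test_tiny_window_identity(self):
        x = np.random.default_rng(16).normal(size=20)
        assert np.array_equal(smooth_for_display(x, 100.0, window_ms=10), x)
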