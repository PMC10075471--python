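"""Permutation inference: sign-flip tests, clusters, cross-correlation, robust r."""

import itertools

import numpy as np
import pytest

from serialdep.permstats import (
    bootstrap_peak_lag,
    cluster_permutation,
    corr_with_outliers,
    crosscorr_lagged,
    crosscorr_null_threshold,
    signflip_pointwise,
)


class TestSignFlip:
    def test_all_positive_scores_minimal_p(self):
        # only the identity flip (probability 2^-6) ties the observed mean,
        # so p sits at about 1/64, bounded below by 1/(n_perm+1)
        scores = np.full((6, 4), 0.3)
        p = signflip_pointwise(scores, n_perm=999, tail="greater", seed=0)
        assert (p >= 1.0 / 1000.0).all()
        assert np.allclose(p, 1.0 / 64.0, atol=0.015)

    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo p agrees with the exact 2^5 sign-flip distribution."""
        rng = np.random.default_rng(1)
        scores = rng.normal(0.3, 1.0, size=(5, 3))
        obs = scores.mean(axis=0)
        exact = []
        for t in range(3):
            col = scores[:, t]
            means = [
                (col * np.array(signs)).mean()
                for signs in itertools.product([1, -1], repeat=5)
            ]
            exact.append(np.mean(np.array(means) >= obs[t]))
        p = signflip_pointwise(scores, n_perm=20000, tail="greater", seed=2)
        assert np.allclose(p, exact, atol=0.02)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = [
            signflip_pointwise(
                rng.normal(size=(8, 1)), n_perm=400, tail="greater", seed=s
            )[0]
            for s in range(200)
        ]
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_nperm_warns(self):
        with pytest.warns(UserWarning, match="resolution"):
            signflip_pointwise(np.random.default_rng(4).normal(size=(4, 2)), n_perm=50)


class TestClusterPermutation:
    def test_planted_window_detected(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, size=(12, 60))
        scores[:, 20:35] += 1.2
        res = cluster_permutation(scores, n_perm=500, tail="greater", seed=0)
        sig = res.significant(0.05)
        assert len(sig) >= 1
        big = max(sig, key=lambda c: abs(c["mass"]))
        assert big["start_idx"] <= 22 and big["end_idx"] >= 32

    def test_negation_with_flipped_tail_symmetric(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(0.2, 1, size=(10, 40))
        a = cluster_permutation(scores, n_perm=300, tail="greater", seed=1)
        b = cluster_permutation(-scores, n_perm=300, tail="less", seed=1)
        assert [(c["start_idx"], c["end_idx"]) for c in a.clusters] == [
            (c["start_idx"], c["end_idx"]) for c in b.clusters
        ]
        assert np.allclose(
            [c["corrected_p"] for c in a.clusters],
            [c["corrected_p"] for c in b.clusters],
        )

    def test_pure_noise_fwer_near_alpha(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_exp = 150
        for _ in range(n_exp):
            scores = rng.normal(size=(10, 30))
            res = cluster_permutation(scores, n_perm=250, tail="greater", seed=8)
            hits += bool(res.significant(0.05))
        rate = hits / n_exp
        assert 0.005 <= rate <= 0.12  # binomial range around 5%

    def test_no_suprathreshold_points_empty_list(self):
        scores = np.random.default_rng(9).normal(0, 0.001, size=(6, 10)) - 10.0
        res = cluster_permutation(scores, n_perm=200, tail="greater", seed=0)
        assert res.clusters == []

    def test_mass_monotone_in_amplitude(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(10, 50))
        masses = []
        for amp in (0.5, 1.0, 2.0):
            scores = base.copy()
            scores[:, 10:30] += amp
            res = cluster_permutation(scores, n_perm=200, tail="greater", seed=1)
            masses.append(max((c["mass"] for c in res.clusters), default=0.0))
        assert masses[0] < masses[1] < masses[2]


class TestCrossCorrelation:
    def test_identical_series_peak_at_zero(self):
        x = np.sin(np.linspace(0, 6 * np.pi, 200))
        res = crosscorr_lagged(x, x, 100.0, 0.5)
        assert res.peak_lag_s == 0.0
        assert res.coefficients.max() == pytest.approx(1.0)

    def test_shifted_series_negative_peak_lag(self):
        """tc2 delayed by +250 ms peaks at −250 ms (tc1 leads)."""
        rng = np.random.default_rng(11)
        base = np.convolve(rng.normal(size=300), np.ones(10) / 10, mode="same")
        shift = 25  # samples at 100 Hz
        tc1 = base[: 250]
        tc2 = np.r_[np.zeros(shift), base[: 250 - shift]]
        res = crosscorr_lagged(tc1, tc2, 100.0, 0.5)
        assert res.peak_lag_s == pytest.approx(-0.25, abs=0.011)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            crosscorr_lagged(np.ones(50), np.random.default_rng(0).normal(size=50), 100.0, 0.1)

    def test_orthogonal_noise_below_threshold(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(40):
            x, y = rng.normal(size=(2, 120))
            res = crosscorr_null_threshold(x, y, 100.0, 0.3, n_perm=200, seed=13)
            hits += bool(res.sig_ranges)
        assert hits / 40 <= 0.2  # max-corrected familywise errors stay rare

    def test_coupled_series_significant_band(self):
        rng = np.random.default_rng(14)
        base = np.convolve(rng.normal(size=400), np.ones(20) / 20, mode="same")
        tc1, tc2 = base[:350], base[:350] + 0.05 * rng.normal(size=350)
        res = crosscorr_null_threshold(tc1, tc2, 100.0, 0.3, n_perm=300, seed=15)
        assert res.sig_ranges
        lo, hi = res.sig_ranges[0][0], res.sig_ranges[-1][1]
        assert lo <= 0.0 <= hi

    def test_single_perm_warns(self):
        rng = np.random.default_rng(16)
        with pytest.warns(UserWarning, match="degenerate"):
            crosscorr_null_threshold(
                rng.normal(size=60), rng.normal(size=60), 100.0, 0.1, n_perm=1
            )


class TestBootstrapPeakLag:
    def _coupled_subjects(self, n_sub, shift_samples, seed, T=220):
        rng = np.random.default_rng(seed)
        base = np.convolve(rng.normal(size=T + 60), np.ones(15) / 15, mode="same")
        a = np.stack([base[:T] + 0.2 * rng.normal(size=T) for _ in range(n_sub)])
        b = np.stack(
            [
                np.r_[np.zeros(shift_samples), base[: T - shift_samples]]
                + 0.2 * rng.normal(size=T)
                for _ in range(n_sub)
            ]
        )
        return a, b

    def test_zero_offset_ci_contains_zero(self):
        a, b = self._coupled_subjects(10, 0, seed=17)
        res = bootstrap_peak_lag(a, b, 100.0, 0.4, n_boot=300, seed=0)
        assert res["ci_low_s"] <= 0.0 <= res["ci_high_s"]
        assert res["ci_high_s"] - res["ci_low_s"] < 0.2

    def test_planted_offset_covered(self):
        a, b = self._coupled_subjects(10, 10, seed=18)
        res = bootstrap_peak_lag(a, b, 100.0, 0.4, n_boot=300, seed=1)
        assert res["ci_low_s"] <= -0.10 <= res["ci_high_s"]

    def test_duplicated_participant_degenerate_ci(self):
        one = np.sin(np.linspace(0, 4 * np.pi, 100))
        a = np.tile(one, (4, 1))
        res = bootstrap_peak_lag(a, a, 100.0, 0.2, n_boot=50, seed=2)
        assert res["ci_low_s"] == res["ci_high_s"] == 0.0

    def test_too_few_participants_refused(self):
        a = np.random.default_rng(19).normal(size=(2, 50))
        with pytest.raises(ValueError, match="3 participants"):
            bootstrap_peak_lag(a, a, 100.0, 0.1, n_boot=10)


class TestCorrWithOutliers:
    def test_perfect_line(self):
        x = np.arange(10, dtype=float)
        res = corr_with_outliers(x, 2 * x + 1)
        assert res["r"] == pytest.approx(1.0)
        assert res["excluded"] == []

    def test_leverage_point_excluded_and_r_restored(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=25)
        y = x + 0.05 * rng.normal(size=25)
        x = np.r_[x, 10.0]
        y = np.r_[y, -10.0]
        res = corr_with_outliers(x, y)
        assert 25 in res["excluded"]
        assert res["r"] > 0.95

    def test_independent_gaussians_p_uniform(self):
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            res = corr_with_outliers(rng.normal(size=20), rng.normal(size=20))
            ps.append(res["p"])
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_refuses_tiny_samples(self):
        with pytest.raises(ValueError, match="remain"):
            corr_with_outliers([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
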