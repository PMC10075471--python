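"""Group-level nonparametric inference for decoding/shift timecourses.

Sign-flip permutation tests (each participant's timecourse is flipped with
probability 1/2 under the null of zero mean), cluster-based correction over
time (suprathreshold cluster mass against the max-cluster null), lagged
cross-correlation with a max-statistic permutation threshold, bootstrap
confidence intervals for cross-correlation peak lags, and Pearson
correlations with an explicit, reported outlier rule.

The cluster-forming threshold is applied on the group-mean statistic at the
pointwise permutation alpha, and cluster mass is the sum of the group mean
over the cluster (a t-mass variant is available).  All p-values include the
observed statistic in the null (p >= 1/(n_perm+1)), making them valid by
construction under exchangeability.

A caution for the cross-correlation null: shuffling samples across time
destroys autocorrelation, which makes the threshold anticonservative for
smooth timecourses; a phase-randomization null that preserves the power
spectrum is provided as an alternative (``method="phase"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterResult",
    "XCorrResult",
    "signflip_pointwise",
    "cluster_permutation",
    "crosscorr_lagged",
    "crosscorr_null_threshold",
    "bootstrap_peak_lag",
    "corr_with_outliers",
]

_TAILS = ("greater", "less", "two-sided")


def _check_scores(scores: np.ndarray) -> np.ndarray:
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    return scores


def _null_means(scores: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """(n_perm, T) group means under independent participant sign flips."""
    n_sub = scores.shape[0]
    signs = rng.integers(0, 2, size=(n_perm, n_sub)) * 2 - 1
    return (signs @ scores) / n_sub


def signflip_pointwise(
    subject_scores: np.ndarray,
    n_perm: int = 10000,
    tail: str = "greater",
    seed: int = 0,
) -> np.ndarray:
    """Pointwise sign-flip permutation p-values for participants x time scores.

    ``tail="greater"`` tests mean > 0 (the decoding convention), ``"less"``
    mean < 0, ``"two-sided"`` |mean| > 0.  The observed statistic is included
    in the null, so p is never smaller than ``1/(n_perm+1)``.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    scores = _check_scores(subject_scores)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    rng = np.random.default_rng(seed)
    null = _null_means(scores, n_perm, rng)
    obs = scores.mean(axis=0)
    if tail == "greater":
        count = (null >= obs).sum(axis=0)
    elif tail == "less":
        count = (null <= obs).sum(axis=0)
    else:
        count = (np.abs(null) >= np.abs(obs)).sum(axis=0)
    return (1.0 + count) / (n_perm + 1.0)


@dataclass
class ClusterResult:
    """Cluster-corrected sign-flip permutation test of a group timecourse."""

    clusters: list[dict]  # start_s, end_s, start_idx, end_idx, mass, corrected_p
    pointwise_p: np.ndarray
    n_perm: int
    tail: str
    alpha_cluster: float
    times: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[dict]:
        return [c for c in self.clusters if c["corrected_p"] < alpha]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop inclusive."""
    if not mask.any():
        return []
    padded = np.r_[False, mask, False].astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts, stops))


def _max_cluster_mass(values: np.ndarray, hi: np.ndarray, lo: np.ndarray | None) -> float:
    """Largest |sum of values| over suprathreshold runs (both signs if lo given)."""
    best = 0.0
    for s, e in _runs(values > hi):
        best = max(best, abs(values[s : e + 1].sum()))
    if lo is not None:
        for s, e in _runs(values < lo):
            best = max(best, abs(values[s : e + 1].sum()))
    return best


def cluster_permutation(
    subject_scores: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    tail: str = "greater",
    seed: int = 0,
    times: np.ndarray | None = None,
    use_t_mass: bool = False,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test over time.

    Clusters are maximal runs where the pointwise statistic exceeds its
    permutation distribution at ``alpha_cluster``; their mass (sum of the
    group mean, or of the one-sample t if ``use_t_mass``) is compared against
    the permutation distribution of the maximum cluster mass.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    scores = _check_scores(subject_scores)
    n_sub, T = scores.shape
    times = np.arange(T, dtype=float) if times is None else np.asarray(times)
    rng = np.random.default_rng(seed)

    if use_t_mass:
        def stat(x):
            m = x.mean(axis=-2)
            sd = x.std(axis=-2, ddof=1)
            return m / np.maximum(sd / np.sqrt(n_sub), 1e-30)
        signs = rng.integers(0, 2, size=(n_perm, n_sub, 1)) * 2 - 1
        null = stat(signs * scores[None])
        obs = stat(scores)
    else:
        null = _null_means(scores, n_perm, rng)
        obs = scores.mean(axis=0)

    # pointwise p of the observed statistic
    if tail == "greater":
        pointwise = (1.0 + (null >= obs).sum(axis=0)) / (n_perm + 1.0)
        hi = np.quantile(null, 1.0 - alpha_cluster, axis=0)
        lo = None
    elif tail == "less":
        pointwise = (1.0 + (null <= obs).sum(axis=0)) / (n_perm + 1.0)
        hi = None
        lo = np.quantile(null, alpha_cluster, axis=0)
    else:
        pointwise = (1.0 + (np.abs(null) >= np.abs(obs)).sum(axis=0)) / (n_perm + 1.0)
        hi = np.quantile(null, 1.0 - alpha_cluster / 2.0, axis=0)
        lo = np.quantile(null, alpha_cluster / 2.0, axis=0)

    if tail == "less":
        obs_runs = _runs(obs < lo)
    elif tail == "greater":
        obs_runs = _runs(obs > hi)
    else:
        obs_runs = sorted(_runs(obs > hi) + _runs(obs < lo))

    null_max = np.empty(n_perm)
    hi_arr = hi if hi is not None else np.full(T, np.inf)
    lo_arr = lo if lo is not None else None
    if tail == "less":
        hi_arr = np.full(T, np.inf)
        lo_arr = lo
    for r in range(n_perm):
        null_max[r] = _max_cluster_mass(null[r], hi_arr, lo_arr)

    clusters = []
    for s, e in obs_runs:
        mass = float(obs[s : e + 1].sum())
        corrected = float((1.0 + (null_max >= abs(mass)).sum()) / (n_perm + 1.0))
        clusters.append(
            {
                "start_idx": int(s),
                "end_idx": int(e),
                "start_s": float(times[s]),
                "end_s": float(times[e]),
                "mass": mass,
                "corrected_p": corrected,
            }
        )
    return ClusterResult(
        clusters=clusters,
        pointwise_p=pointwise,
        n_perm=n_perm,
        tail=tail,
        alpha_cluster=alpha_cluster,
        times=times,
    )


# ---------------------------------------------------------------------------
# Cross-correlation
# ---------------------------------------------------------------------------


@dataclass
class XCorrResult:
    """Lagged cross-correlation with max-statistic permutation threshold."""

    lags_s: np.ndarray
    coefficients: np.ndarray
    peak_lag_s: float
    threshold: float | None = None
    significant: np.ndarray | None = None
    sig_ranges: list[tuple[float, float]] = field(default_factory=list)
    peak_ci: tuple[float, float] | None = None


def crosscorr_lagged(
    tc1: np.ndarray,
    tc2: np.ndarray,
    sampling_rate: float,
    max_lag_s: float,
    demean: bool = True,
) -> XCorrResult:
    """Normalized cross-correlation of two equal-grid timecourses.

    Sign convention: ``c(lag) = sum_t tc1[t] * tc2[t - lag]`` with full-series
    energy normalization, so a *negative* peak lag means tc1 leads tc2.
    Overlap shrinks toward the extreme lags (zero padding); coefficients stay
    in [−1, 1].
    """
    x = np.asarray(tc1, dtype=float)
    y = np.asarray(tc2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("tc1 and tc2 must be equal-length 1-D series")
    if demean:
        x = x - x.mean()
        y = y - y.mean()
    if np.allclose(x, 0) or np.allclose(y, 0):
        raise ValueError("constant series: cross-correlation undefined")
    T = len(x)
    L = int(round(max_lag_s * sampling_rate))
    L = min(L, T - 1)
    lags = np.arange(-L, L + 1)
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    coefs = np.empty(len(lags))
    for i, ell in enumerate(lags):
        if ell >= 0:
            coefs[i] = np.dot(x[ell:], y[: T - ell]) / denom
        else:
            coefs[i] = np.dot(x[: T + ell], y[-ell:]) / denom
    peak = lags[int(np.argmax(coefs))] / sampling_rate
    return XCorrResult(
        lags_s=lags / sampling_rate, coefficients=coefs, peak_lag_s=float(peak)
    )


def crosscorr_null_threshold(
    tc1: np.ndarray,
    tc2: np.ndarray,
    sampling_rate: float,
    max_lag_s: float,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "shuffle",
) -> XCorrResult:
    """Max-corrected permutation threshold for the lagged cross-correlation.

    Each permutation shuffles both series across time (``method="shuffle"``,
    the literal procedure) or phase-randomizes them (``method="phase"``,
    autocorrelation-preserving alternative), recomputes the cross-correlation
    and records its maximum over lags; the threshold is the ``1 - alpha``
    quantile of those maxima.
    """
    if n_perm < 2:
        warnings.warn("n_perm < 2 gives a degenerate threshold")
    if method not in ("shuffle", "phase"):
        raise ValueError("method must be 'shuffle' or 'phase'")
    rng = np.random.default_rng(seed)
    obs = crosscorr_lagged(tc1, tc2, sampling_rate, max_lag_s)
    x = np.asarray(tc1, dtype=float)
    y = np.asarray(tc2, dtype=float)
    maxima = np.empty(max(n_perm, 1))
    for r in range(max(n_perm, 1)):
        if method == "shuffle":
            xp = x[rng.permutation(len(x))]
            yp = y[rng.permutation(len(y))]
        else:
            xp = _phase_randomize(x, rng)
            yp = _phase_randomize(y, rng)
        c = crosscorr_lagged(xp, yp, sampling_rate, max_lag_s)
        maxima[r] = c.coefficients.max()
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    sig = obs.coefficients > threshold
    ranges = [
        (float(obs.lags_s[s]), float(obs.lags_s[e])) for s, e in _runs(sig)
    ]
    return XCorrResult(
        lags_s=obs.lags_s,
        coefficients=obs.coefficients,
        peak_lag_s=obs.peak_lag_s,
        threshold=threshold,
        significant=sig,
        sig_ranges=ranges,
    )


def _phase_randomize(x: np.ndarray, rng) -> np.ndarray:
    spec = np.fft.rfft(x - x.mean())
    phases = rng.uniform(0, 2 * np.pi, len(spec))
    phases[0] = 0.0
    out = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=len(x))
    return out + x.mean()


def bootstrap_peak_lag(
    subj_tc1: np.ndarray,
    subj_tc2: np.ndarray,
    sampling_rate: float,
    max_lag_s: float,
    n_boot: int = 5000,
    seed: int = 0,
) -> dict:
    """Participant-bootstrap CI for the cross-correlation peak lag.

    Resamples participants with replacement, recomputes the group-mean
    timecourses and their cross-correlation peak; the CI is the 2.5/97.5
    percentile of the resampled peak lags.
    """
    a = _check_scores(subj_tc1)
    b = _check_scores(subj_tc2)
    if a.shape != b.shape:
        raise ValueError("the two participant arrays must have matching shapes")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 participants to bootstrap")
    rng = np.random.default_rng(seed)
    obs = crosscorr_lagged(a.mean(axis=0), b.mean(axis=0), sampling_rate, max_lag_s)
    n_sub = a.shape[0]
    peaks = np.empty(n_boot)
    for r in range(n_boot):
        take = rng.integers(0, n_sub, n_sub)
        c = crosscorr_lagged(
            a[take].mean(axis=0), b[take].mean(axis=0), sampling_rate, max_lag_s
        )
        peaks[r] = c.peak_lag_s
    lo, hi = np.percentile(peaks, [2.5, 97.5])
    return {
        "peak_lag_s": obs.peak_lag_s,
        "ci_low_s": float(lo),
        "ci_high_s": float(hi),
        "boot_peaks_s": peaks,
    }


# ---------------------------------------------------------------------------
# Behavior-brain correlation with outlier handling
# ---------------------------------------------------------------------------


def corr_with_outliers(
    x,
    y,
    sd_threshold: float = 3.0,
    iterations: int = 1,
    min_n: int = 5,
) -> dict:
    """Pearson correlation after excluding extreme points, exclusions reported.

    Points beyond ``sd_threshold`` standard deviations from the mean on
    either axis are removed; the rule is applied ``iterations`` times
    (recomputing means/SDs on the survivors).  Refuses to correlate fewer
    than ``min_n`` surviving points.
    """
    xs = pd.Series(x).astype(float)
    ys = pd.Series(y).astype(float)
    if not xs.index.equals(ys.index):
        ys.index = xs.index
    keep = xs.notna() & ys.notna()
    for _ in range(iterations):
        xv, yv = xs[keep], ys[keep]
        if xv.std(ddof=1) > 0:
            keep &= (xs - xv.mean()).abs() <= sd_threshold * xv.std(ddof=1)
        if yv.std(ddof=1) > 0:
            keep &= (ys - yv.mean()).abs() <= sd_threshold * yv.std(ddof=1)
    excluded = list(xs.index[~keep])
    n_used = int(keep.sum())
    if n_used < min_n:
        raise ValueError(f"only {n_used} points remain after outlier exclusion")
    r, p = stats.pearsonr(xs[keep], ys[keep])
    return {
        "r": float(r),
        "p": float(p),
        "n": n_used,
        "excluded": excluded,
        "sd_threshold": sd_threshold,
    }
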