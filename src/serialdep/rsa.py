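"""Time-resolved cross-validated Mahalanobis RSA decoding.

At each time point t, voltages over channels and a short trailing window
(default 2 samples: t−1 and t, i.e. 20 ms at 100 Hz) are pooled into one
spatiotemporal pattern per trial.  Within a stratified k-fold scheme
(repeated with fresh randomness and averaged), condition templates are the
means of a *balanced* training subsample, the noise covariance is estimated
from the condition-demeaned training trials with a Ledoit-Wolf shrinkage
estimator, and each held-out trial's Mahalanobis distance to every template
is computed.  The decoding score at t is the mean over trials of the OLS
slope of a trial's template distances on dummy-coded feature dissimilarity
(0 = same condition, 1 = different), which for balanced designs equals
mean(distance to other conditions) − distance to own condition; values above
0 indicate that the feature is represented.

Past/future-trial features are decoded *conditionally*: within each stratum
of the confounding feature (e.g. within each current pitch when decoding the
previous pitch), then averaged across strata, so that current-trial encoding
cannot leak into history decoding.

All inner loops are batched over time with stacked covariance/Cholesky
operations; the per-matrix :func:`shrinkage_covariance` is the same estimator
and is cross-checked against scikit-learn's LedoitWolf in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from serialdep.io import EpochSet

logger = logging.getLogger(__name__)


def _isnull(arr) -> np.ndarray:
    """NaN mask that also works for object/string label arrays."""
    import pandas as pd

    return np.asarray(pd.isnull(arr))


@dataclass
class DecodingConfig:
    """Knobs of the cross-validated distance computation.

    ``window_samples=2`` reproduces the standard 20-ms (t−1, t) spatiotemporal
    window at 100 Hz; ``shrinkage`` is ``"auto"`` (Ledoit-Wolf) or a fixed
    coefficient in [0, 1] (0 = raw sample covariance, for oracle checks).
    ``time_step`` decodes every k-th sample (1 = the full grid).
    """

    window_samples: int = 2
    n_folds: int = 8
    n_reps: int = 50
    balance: bool = True
    shrinkage: str | float = "auto"
    time_step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.window_samples < 1:
            raise ValueError("window_samples must be >= 1")
        if not (
            self.shrinkage == "auto"
            or (np.isscalar(self.shrinkage) and 0.0 <= float(self.shrinkage) <= 1.0)
        ):
            raise ValueError("shrinkage must be 'auto' or a value in [0, 1]")


@dataclass
class DecodingTimecourse:
    """Per-timepoint decoding score for one participant and feature."""

    feature: str
    times: np.ndarray
    score: np.ndarray
    n_trials: int
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Pattern extraction
# ---------------------------------------------------------------------------


def spatiotemporal_patterns(
    epochs: EpochSet, t_index: int, window_samples: int
) -> np.ndarray:
    """Trials x (channels*window) pattern matrix at sample ``t_index``.

    Column order is sample-major: all channels at the earliest window sample
    first, channels at ``t_index`` last.
    """
    n_samples = epochs.data.shape[2]
    if not window_samples - 1 <= t_index < n_samples:
        raise IndexError(
            f"t_index {t_index} out of range for window {window_samples} "
            f"and {n_samples} samples"
        )
    sl = epochs.data[:, :, t_index - window_samples + 1 : t_index + 1]
    # (trials, channels, window) -> sample-major concatenation
    return sl.transpose(0, 2, 1).reshape(len(sl), -1)


def _window_stack(data: np.ndarray, t_indices: np.ndarray, window: int) -> np.ndarray:
    """(trials, T, channels*window) patterns for many timepoints at once."""
    n, c, _ = data.shape
    cols = []
    for k in range(window - 1, -1, -1):
        cols.append(data[:, :, t_indices - k])  # (n, c, T)
    stacked = np.stack(cols, axis=1)  # (n, window, c, T) sample-major
    return stacked.reshape(n, window * c, len(t_indices)).transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# Shrinkage covariance (batched Ledoit-Wolf)
# ---------------------------------------------------------------------------


def _lw_covariance_batched(Xc: np.ndarray, shrinkage) -> np.ndarray:
    """Covariances for centered data ``(n, T, p)`` -> ``(T, p, p)``.

    Ledoit-Wolf shrinkage toward the scaled identity; divisor ``n``
    (data are treated as already centered).
    """
    n, T, p = Xc.shape
    S = np.einsum("ntp,ntq->tpq", Xc, Xc) / n
    mu = np.trace(S, axis1=1, axis2=2) / p  # (T,)
    eye = np.eye(p)
    dev = S - mu[:, None, None] * eye
    d2 = np.einsum("tpq,tpq->t", dev, dev)
    if shrinkage == "auto":
        sq_norms = np.einsum("ntp,ntp->nt", Xc, Xc)  # |x_k|^2 per trial
        S2 = np.einsum("tpq,tpq->t", S, S)
        b2 = (sq_norms**2).sum(axis=0) / n**2 - S2 / n
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(d2 > 0, np.minimum(b2, d2) / d2, 1.0)
    else:
        rho = np.full(T, float(shrinkage))
    out = (1.0 - rho)[:, None, None] * S + (rho * mu)[:, None, None] * eye
    return out


def shrinkage_covariance(X: np.ndarray, shrinkage="auto") -> np.ndarray:
    """Ledoit-Wolf-regularized covariance of ``(samples, features)`` data.

    The mean is removed first; with ``shrinkage="auto"`` the result is SPD
    even for constant features or p > n.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0)
    cov = _lw_covariance_batched(Xc[:, None, :], shrinkage)[0]
    return cov


# ---------------------------------------------------------------------------
# Cross-validated distances
# ---------------------------------------------------------------------------


def _stratified_folds(labels: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Round-robin fold ids per condition; every fold sees every condition."""
    fold_ids = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        fold_ids[idx] = np.arange(len(idx)) % n_folds
    return fold_ids


def mahalanobis_to_templates(
    train_X: np.ndarray,
    train_labels: np.ndarray,
    test_X: np.ndarray,
    conditions: Sequence,
    shrinkage="auto",
) -> np.ndarray:
    """Distances from test trials to condition templates, one train/test split.

    Templates are condition means of the training trials; the covariance is
    estimated from the condition-demeaned training trials (pooled) with the
    requested shrinkage.  Accepts ``(n, p)`` or batched ``(n, T, p)`` inputs;
    returns ``(n_test, C)`` or ``(n_test, T, C)``.
    """
    squeeze = train_X.ndim == 2
    if squeeze:
        train_X = train_X[:, None, :]
        test_X = test_X[:, None, :]
    C = len(conditions)
    _, T, p = train_X.shape
    means = np.stack(
        [train_X[train_labels == c].mean(axis=0) for c in conditions]
    )  # (C, T, p)
    cond_pos = np.searchsorted(np.asarray(conditions), train_labels)
    resid = train_X - means[cond_pos]
    cov = _lw_covariance_batched(resid, shrinkage)  # (T, p, p)
    cov = cov + 1e-12 * np.trace(cov, axis1=1, axis2=2)[:, None, None] * np.eye(p)
    L = np.linalg.cholesky(cov)
    Linv = np.linalg.inv(L)
    diffs = test_X[:, :, None, :] - means.transpose(1, 0, 2)[None]  # (n, T, C, p)
    wh = np.einsum("tpq,ntcq->ntcp", Linv, diffs)
    d = np.sqrt(np.einsum("ntcp,ntcp->ntc", wh, wh))
    return d[:, 0, :] if squeeze else d


def crossval_distances(
    patterns: np.ndarray, labels: np.ndarray, cfg: DecodingConfig, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated stratified k-fold Mahalanobis distances to condition templates.

    ``patterns`` is ``(n, p)`` or ``(n, T, p)``.  Returns ``(distances,
    conditions)`` with distances ``(n, C)`` / ``(n, T, C)`` averaged over
    ``cfg.n_reps`` repetitions.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    patterns = np.asarray(patterns, dtype=float)
    squeeze = patterns.ndim == 2
    X = patterns[:, None, :] if squeeze else patterns
    labels = np.asarray(labels)
    conditions = np.unique(labels)
    counts = {c: int((labels == c).sum()) for c in conditions}
    too_few = [c for c, k in counts.items() if k < cfg.n_folds]
    if too_few:
        raise ValueError(
            f"conditions {too_few} have fewer trials than n_folds={cfg.n_folds}"
        )
    n, T, p = X.shape
    acc = np.zeros((n, T, len(conditions)))
    for _ in range(cfg.n_reps):
        fold_ids = _stratified_folds(labels, cfg.n_folds, rng)
        for f in range(cfg.n_folds):
            test = fold_ids == f
            train = ~test
            tr_idx = np.flatnonzero(train)
            tr_labels = labels[tr_idx]
            if cfg.balance:
                m = min(int((tr_labels == c).sum()) for c in conditions)
                keep = []
                for c in conditions:
                    pool = tr_idx[tr_labels == c]
                    keep.append(rng.choice(pool, size=m, replace=False))
                tr_idx = np.concatenate(keep)
                tr_labels = labels[tr_idx]
                used = [int((tr_labels == c).sum()) for c in conditions]
                assert len(set(used)) == 1, "training subsample not balanced"
            acc[test] += mahalanobis_to_templates(
                X[tr_idx], tr_labels, X[test], conditions, cfg.shrinkage
            )
    acc /= cfg.n_reps
    return (acc[:, 0, :] if squeeze else acc), conditions


def distance_regression_score(
    distances: np.ndarray, labels: np.ndarray, conditions: np.ndarray
) -> np.ndarray | float:
    """Mean per-trial OLS slope of template distances on dissimilarity codes.

    The dissimilarity predictor is 0 for the trial's own condition and 1 for
    every other, so the per-trial slope equals mean(other-condition
    distances) − own-condition distance; for two conditions this reduces to
    the plain distance difference.  Positive values indicate feature
    information.
    """
    distances = np.asarray(distances, dtype=float)
    squeeze = distances.ndim == 2
    d = distances[:, None, :] if squeeze else distances
    pos = np.searchsorted(np.asarray(conditions), np.asarray(labels))
    n, T, C = d.shape
    own = d[np.arange(n), :, pos]
    other = (d.sum(axis=2) - own) / (C - 1)
    slope = (other - own).mean(axis=0)
    return float(slope[0]) if squeeze else slope


def regress_out_condition(patterns: np.ndarray, confound_labels: np.ndarray) -> np.ndarray:
    """Remove confound-level means from patterns, keeping the grand mean.

    Equivalent to residualizing each feature column on dummy-coded confound
    levels; for a categorical confound the OLS projection is exactly the
    per-level mean subtraction performed here.
    """
    patterns = np.asarray(patterns, dtype=float)
    labels = np.asarray(confound_labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        warnings.warn("confound has a single level; returning patterns unchanged")
        return patterns.copy()
    out = patterns.copy()
    grand = patterns.mean(axis=0)
    for lev in levels:
        m = labels == lev
        out[m] -= patterns[m].mean(axis=0) - grand
    return out


# ---------------------------------------------------------------------------
# Timecourses
# ---------------------------------------------------------------------------


def _valid_time_indices(epochs: EpochSet, cfg: DecodingConfig) -> np.ndarray:
    return np.arange(cfg.window_samples - 1, epochs.data.shape[2], cfg.time_step)


def decode_timecourse(
    epochs: EpochSet,
    labels: np.ndarray,
    cfg: DecodingConfig,
    confound_labels: np.ndarray | None = None,
    feature: str = "feature",
    rng=None,
) -> DecodingTimecourse:
    """Time-resolved decoding score for one participant.

    Timepoints without a full trailing window are trimmed (not padded).  With
    ``confound_labels`` the confound's level means are regressed out of the
    patterns at every timepoint before distances are computed.
    """
    labels = np.asarray(labels)
    if np.any(_isnull(labels)):
        raise ValueError("labels must be defined for all trials")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    t_idx = _valid_time_indices(epochs, cfg)
    Xw = _window_stack(epochs.data, t_idx, cfg.window_samples)
    if confound_labels is not None:
        Xw = regress_out_condition(Xw, confound_labels)
    dists, conditions = crossval_distances(Xw, labels, cfg, rng=rng)
    score = distance_regression_score(dists, labels, conditions)
    return DecodingTimecourse(
        feature=feature,
        times=epochs.times[t_idx],
        score=np.asarray(score),
        n_trials=len(labels),
        provenance={
            "window_samples": cfg.window_samples,
            "n_folds": cfg.n_folds,
            "n_reps": cfg.n_reps,
            "shrinkage": cfg.shrinkage,
            "conditions": np.asarray(conditions).tolist(),
        },
    )


def conditional_decode_timecourse(
    epochs: EpochSet,
    target_labels: np.ndarray,
    strata_labels: np.ndarray,
    cfg: DecodingConfig,
    confound_labels: np.ndarray | None = None,
    feature: str = "feature",
    stratum_weights: str = "equal",
    rng=None,
) -> DecodingTimecourse:
    """Decode a feature while fixing another: stratify, decode, average.

    Each stratum must retain every target condition with at least ``n_folds``
    trials; strata failing this are skipped (logged).  Scores are averaged
    over strata with equal weights (``stratum_weights="size"`` weights by
    stratum trial count instead).
    """
    if stratum_weights not in ("equal", "size"):
        raise ValueError("stratum_weights must be 'equal' or 'size'")
    target_labels = np.asarray(target_labels)
    strata_labels = np.asarray(strata_labels)
    if np.any(_isnull(target_labels)) or np.any(_isnull(strata_labels)):
        raise ValueError("target and strata labels must be defined for all trials")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    conditions = np.unique(target_labels)
    scores = []
    used_strata = []
    sizes = []
    times = None
    n_used = 0
    for s in np.unique(strata_labels):
        m = strata_labels == s
        sub_counts = [(target_labels[m] == c).sum() for c in conditions]
        if min(sub_counts) < cfg.n_folds:
            logger.info("stratum %r skipped (min condition count %d)", s, min(sub_counts))
            continue
        tc = decode_timecourse(
            epochs.subset(m),
            target_labels[m],
            cfg,
            confound_labels=None if confound_labels is None else confound_labels[m],
            feature=feature,
            rng=rng,
        )
        scores.append(tc.score)
        used_strata.append(s)
        sizes.append(int(m.sum()))
        times = tc.times
        n_used += int(m.sum())
    if not scores:
        raise ValueError("all strata skipped; conditional decoding impossible")
    weights = None if stratum_weights == "equal" else np.asarray(sizes, dtype=float)
    return DecodingTimecourse(
        feature=feature,
        times=times,
        score=np.average(scores, axis=0, weights=weights),
        n_trials=n_used,
        provenance={"strata": [str(s) for s in used_strata], "n_strata": len(scores)},
    )


def smooth_for_display(
    values: np.ndarray, sampling_rate: float, window_ms: float = 150.0
) -> np.ndarray:
    """Gaussian-weighted moving average for plotting (never for inference).

    The kernel spans ``window_ms`` with sigma = window/5 (the common
    moving-average convention) and is renormalized at the edges, so constant
    inputs are preserved exactly.  Windows shorter than 2 samples return the
    input unchanged.
    """
    values = np.asarray(values, dtype=float)
    w = int(round(window_ms / 1000.0 * sampling_rate))
    if w < 2:
        return values.copy()
    half = w // 2
    x = np.arange(-half, half + 1)
    sigma = w / 5.0
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


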