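"""Representational-shift statistic (Shift_dist).

Quantifies whether the neural representation of the current trial's feature
is displaced *toward* (attraction, positive) or *away from* (repulsion,
negative) the previous trial's feature.

For a multi-level feature such as pitch, consider an ordered level pair
(a, b), a ≠ b.  Cross-validated condition templates are built for a and b,
and every trial's Mahalanobis distances D1 (to template a) and D2 (to
template b) are computed with the same fold machinery as the decoder.  Over
trials with current = a and previous = b, M_diff = mean(D2 − D1); over the
baseline trials with current = a and previous = a, M_diff_baseline =
mean(D2 − D1).  Shift_dist(a, b) = M_diff_baseline − M_diff: if the previous
b pulls the representation of a toward b, D2 shrinks, M_diff drops below
baseline, and Shift_dist is positive.  The participant's timecourse averages
Shift_dist over all ordered pairs with data (each pair's baseline shares the
current level, so current-trial encoding cancels by construction).

For binary features (category choice, motor response) the two templates are
built once and each trial's signed distance difference is oriented so that
attraction toward the *previous* level is positive (previous "high":
d(low) − d(high); previous "low": the mirror).  Orientation means are taken
within (previous x current) cells and averaged with equal cell weights; this
equals the classic trial-pooled average under a balanced design but stays
centered at zero when behavioral serial bias makes current labels uneven
across previous-label groups, so behavior alone cannot mimic a neural shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from serialdep.io import EpochSet
from serialdep.rsa import (
    DecodingConfig,
    _isnull,
    _valid_time_indices,
    _window_stack,
    crossval_distances,
    regress_out_condition,
)

logger = logging.getLogger(__name__)


@dataclass
class ShiftTimecourse:
    """Per-timepoint Shift_dist for one participant and feature.

    ``shift`` is in Mahalanobis distance units; positive = attraction toward
    the previous trial's feature, negative = repulsion.  ``pairs`` holds the
    per-pair bookkeeping (M_diff, M_diff_baseline and cell sizes for the
    multi-level analysis; per-orientation differences for binary features).
    """

    feature: str
    times: np.ndarray
    shift: np.ndarray
    n_trials: int
    pairs: dict = field(default_factory=dict)


def _cv_distance_stack(
    epochs: EpochSet,
    labels: np.ndarray,
    cfg: DecodingConfig,
    confound_labels: np.ndarray | None,
    rng,
):
    """(n, T, C) CV distances to current-feature templates + times/conditions."""
    t_idx = _valid_time_indices(epochs, cfg)
    Xw = _window_stack(epochs.data, t_idx, cfg.window_samples)
    if confound_labels is not None:
        Xw = regress_out_condition(Xw, confound_labels)
    dists, conditions = crossval_distances(Xw, labels, cfg, rng=rng)
    return dists, epochs.times[t_idx], conditions


def pairwise_shift_pitch(
    epochs: EpochSet,
    current_pitch: np.ndarray,
    prev_pitch: np.ndarray,
    cfg: DecodingConfig,
    confound_labels: np.ndarray | None = None,
    pairs: str = "all",
    feature: str = "pitch",
    rng=None,
) -> ShiftTimecourse:
    """Multi-level Shift_dist averaged over ordered level pairs.

    ``pairs="all"`` (default) uses every ordered pair (a, b) with a ≠ b;
    ``pairs="adjacent"`` restricts to |a − b| = 1.  Pairs whose (current=a,
    previous=b) or baseline (current=a, previous=a) cell is empty are skipped
    and logged; if every pair is skipped an error is raised.  Trials with
    undefined previous pitch contribute to template building but to no cell.
    """
    current_pitch = np.asarray(current_pitch)
    prev = np.asarray(prev_pitch, dtype=float)
    if np.any(_isnull(current_pitch)):
        raise ValueError("current_pitch must be defined for all trials")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    dists, times, conditions = _cv_distance_stack(
        epochs, current_pitch, cfg, confound_labels, rng
    )
    cond_index = {c: i for i, c in enumerate(conditions)}

    pair_curves = []
    bookkeeping = {}
    for a in conditions:
        for b in conditions:
            if a == b:
                continue
            if pairs == "adjacent" and abs(int(a) - int(b)) != 1:
                continue
            cell = (current_pitch == a) & (prev == float(b))
            base = (current_pitch == a) & (prev == float(a))
            if not cell.any() or not base.any():
                logger.info("pair (%s, %s) skipped: empty cell", a, b)
                continue
            d1 = dists[:, :, cond_index[a]]
            d2 = dists[:, :, cond_index[b]]
            m_diff = (d2[cell] - d1[cell]).mean(axis=0)
            m_base = (d2[base] - d1[base]).mean(axis=0)
            curve = m_base - m_diff
            pair_curves.append(curve)
            bookkeeping[(int(a), int(b))] = {
                "m_diff": m_diff,
                "m_diff_baseline": m_base,
                "n_cell": int(cell.sum()),
                "n_baseline": int(base.sum()),
            }
    if not pair_curves:
        raise ValueError("all level pairs skipped; no cells populated")
    return ShiftTimecourse(
        feature=feature,
        times=times,
        shift=np.mean(pair_curves, axis=0),
        n_trials=len(current_pitch),
        pairs=bookkeeping,
    )


def _binary_shift_curve(
    dists: np.ndarray,
    cur: np.ndarray,
    prev: np.ndarray,
    hi_col: int,
    lo_col: int,
) -> tuple[np.ndarray, dict]:
    """Cell-balanced orientation average; None when a required cell is empty."""
    d_hi = dists[:, :, hi_col]
    d_lo = dists[:, :, lo_col]
    signed_hi = d_lo - d_hi  # positive = closer to "high"
    curves = {}
    for prev_level, sign, name in ((1.0, +1.0, "diff_prev_high"), (0.0, -1.0, "diff_prev_low")):
        cell_means = []
        for c in (0, 1):
            cell = (prev == prev_level) & (cur == c)
            if not cell.any():
                return None, {}
            cell_means.append(sign * signed_hi[cell].mean(axis=0))
        curves[name] = np.mean(cell_means, axis=0)
    shift = 0.5 * (curves["diff_prev_high"] + curves["diff_prev_low"])
    return shift, curves


def binary_shift(
    epochs: EpochSet,
    current_binary: np.ndarray,
    prev_binary: np.ndarray,
    cfg: DecodingConfig,
    control_strata: np.ndarray | None = None,
    confound_labels: np.ndarray | None = None,
    feature: str = "category",
    rng=None,
) -> ShiftTimecourse:
    """Shift_dist for a binary feature (category choice or motor response).

    With ``control_strata`` (e.g. response-cue identity when category and
    motor are temporally bound), the analysis runs within each stratum and
    averages the resulting curves; strata with an empty (previous x current)
    cell or too few trials per condition are skipped.
    """
    cur = np.asarray(current_binary, dtype=float)
    prev = np.asarray(prev_binary, dtype=float)
    if np.any(_isnull(current_binary)):
        raise ValueError("current labels must be defined for all trials")
    if len(np.unique(cur)) < 2:
        raise ValueError("binary shift requires both levels in the data")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    strata = (
        np.zeros(len(cur)) if control_strata is None else np.asarray(control_strata)
    )
    curves = []
    details = {}
    times = None
    n_used = 0
    for s in np.unique(strata):
        m = strata == s
        if min((cur[m] == 0).sum(), (cur[m] == 1).sum()) < cfg.n_folds:
            logger.info("stratum %r skipped: too few trials per condition", s)
            continue
        dists, times_s, conditions = _cv_distance_stack(
            epochs.subset(m),
            cur[m],
            cfg,
            None if confound_labels is None else np.asarray(confound_labels)[m],
            rng,
        )
        cond_index = {c: i for i, c in enumerate(conditions)}
        shift, curve_detail = _binary_shift_curve(
            dists, cur[m], prev[m], cond_index[1.0], cond_index[0.0]
        )
        if shift is None:
            logger.info("stratum %r skipped: empty (previous x current) cell", s)
            continue
        curves.append(shift)
        details[s] = curve_detail
        times = times_s
        n_used += int(m.sum())
    if not curves:
        raise ValueError("no usable strata for binary shift analysis")
    return ShiftTimecourse(
        feature=feature,
        times=times,
        shift=np.mean(curves, axis=0),
        n_trials=n_used,
        pairs=details,
    )
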