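"""Trial tables, epoched-data containers, filtering, and file round-trips.

A *trial table* is a :class:`pandas.DataFrame` with one row per trial and a
documented column schema (:data:`REQUIRED_COLUMNS`).  History columns
(``prev_*`` / ``next_*``) are derived within participant by trial-index
adjacency, so removing a trial breaks the chain on both sides: the successor
of a removed trial has no defined previous trial and the predecessor has no
defined next trial.

An :class:`EpochSet` holds a ``trials x channels x samples`` array with a
uniform time axis (seconds, 0 = noise onset by convention), channel labels,
event annotations (e.g. tone and response-cue onsets) and a key-based link
back to trial-table rows, so that any row filtering can be mirrored on the
epochs without positional bookkeeping.

On disk, epochs use a plain array container plus JSON sidecar: ``<base>.npy``
stores the float array (C order, trials x channels x samples) and
``<base>.meta.json`` stores ``{sampling_rate, times, channel_labels, events,
trial_keys}`` where ``trial_keys`` is a list of ``[participant, trial_index]``
pairs.  A converter to/from :class:`mne.EpochsArray` is provided as a
convenience adapter for the wider EEG ecosystem.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mandatory trial-table columns, in canonical order.
REQUIRED_COLUMNS = [
    "participant",
    "block",
    "trial_index",
    "pitch_level",
    "choice",
    "motor_response",
    "cue_mapping",
    "reaction_time",
]

#: Features for which history columns are derived, mapped to short names.
HISTORY_FEATURES = {
    "pitch_level": "pitch",
    "choice": "choice",
    "motor_response": "motor",
}

PITCH_LEVELS = (1, 2, 3, 4, 5)


class SchemaError(ValueError):
    """A mandatory column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """Row-level values violate the trial-table domain."""


class IntegrityError(ValueError):
    """Epoch data and trial metadata are inconsistent."""


@dataclass
class FilterSpec:
    """Trial-exclusion rules.

    Parameters
    ----------
    rt_sd_threshold
        Remove trials whose reaction time exceeds ``mean + k * SD``.  Applied
        per participant (thresholds and speeds are individualized); set
        ``rt_scope="pooled"`` to compute one threshold over all participants.
        ``None`` disables the rule.
    exclude_prev_levels
        Remove trials whose previous pitch level is in this set (e.g. ``{1, 5}``
        to drop trials preceded by the unambiguous extreme pitches).
    require_valid
        Keep only rows whose ``valid`` flag is true (if the column exists).
    """

    rt_sd_threshold: float | None = 4.0
    exclude_prev_levels: frozenset[int] = field(default_factory=frozenset)
    require_valid: bool = True
    rt_scope: str = "participant"  # or "pooled"

    def __post_init__(self) -> None:
        if self.rt_sd_threshold is not None and self.rt_sd_threshold <= 0:
            raise ValueError("rt_sd_threshold must be > 0")
        if self.rt_scope not in ("participant", "pooled"):
            raise ValueError("rt_scope must be 'participant' or 'pooled'")
        self.exclude_prev_levels = frozenset(int(v) for v in self.exclude_prev_levels)


def validate_trial_table(trials: pd.DataFrame) -> None:
    """Check schema and domain invariants, raising on violation."""
    for col in REQUIRED_COLUMNS:
        if col not in trials.columns:
            raise SchemaError(f"trial table is missing mandatory column {col!r}")
    bad_pitch = ~trials["pitch_level"].isin(PITCH_LEVELS)
    if bad_pitch.any():
        rows = trials.index[bad_pitch].tolist()
        raise ValidationError(
            f"pitch_level outside 1..5 in rows {rows[:20]}"
            + (" ..." if len(rows) > 20 else "")
        )
    for col in ("choice", "motor_response", "cue_mapping"):
        bad = ~trials[col].isin((0, 1))
        if bad.any():
            rows = trials.index[bad].tolist()
            raise ValidationError(f"{col} outside {{0,1}} in rows {rows[:20]}")
    dup = trials.duplicated(subset=["participant", "trial_index"])
    if dup.any():
        raise ValidationError(
            f"duplicate (participant, trial_index) keys in rows "
            f"{trials.index[dup].tolist()[:20]}"
        )


def load_trial_table(path: str | Path, derive_history: bool = True) -> pd.DataFrame:
    """Read a delimited trial table (CSV or TSV by extension) and validate it.

    Rows are sorted by ``(participant, trial_index)``; history columns at
    offsets ±1 are derived unless ``derive_history=False``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    trials = pd.read_csv(path, sep=sep)
    validate_trial_table(trials)
    trials = trials.sort_values(["participant", "trial_index"], kind="stable")
    trials = trials.reset_index(drop=True)
    logger.info(
        "loaded %d trials, %d participants from %s",
        len(trials),
        trials["participant"].nunique(),
        path,
    )
    if derive_history:
        trials = derive_history_columns(trials, -1)
        trials = derive_history_columns(trials, +1)
    return trials


def save_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV/TSV (by extension), without the index."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    trials.to_csv(path, sep=sep, index=False)


def _offset_prefix(offset: int) -> str:
    if offset == -1:
        return "prev"
    if offset == 1:
        return "next"
    return f"lag{offset}" if offset < 0 else f"lead{offset}"


def derive_history_columns(
    trials: pd.DataFrame,
    offset: int,
    group_cols: Sequence[str] = ("participant",),
) -> pd.DataFrame:
    """Add feature columns taken from the trial at ``trial_index + offset``.

    The lookup is by trial-index *value* within ``group_cols`` groups, so a
    missing neighbor — participant boundary, or a trial removed by filtering —
    yields NaN ("undefined").  ``offset=-1`` produces ``prev_pitch``,
    ``prev_choice``, ``prev_motor``; ``offset=+1`` the ``next_*`` triplet.
    """
    if offset == 0:
        raise ValueError("offset must be nonzero")
    prefix = _offset_prefix(offset)
    out = trials.copy()
    cols = {f"{prefix}_{short}": np.full(len(out), np.nan) for short in HISTORY_FEATURES.values()}
    grouped = out.groupby(list(group_cols), sort=False)
    for _, idx in grouped.indices.items():
        sub = out.iloc[idx]
        index_of = pd.Series(idx, index=sub["trial_index"].to_numpy())
        wanted = sub["trial_index"].to_numpy() + offset
        hit = index_of.reindex(wanted)
        src_rows = hit.to_numpy()
        ok = ~np.isnan(src_rows)
        if not ok.any():
            warnings.warn(
                f"offset {offset} leaves all history undefined for group "
                f"{tuple(sub[list(group_cols)].iloc[0])}",
                stacklevel=2,
            )
            continue
        src = src_rows[ok].astype(int)
        for col, short in HISTORY_FEATURES.items():
            vals = out[col].to_numpy(dtype=float)
            cols[f"{prefix}_{short}"][idx[ok]] = vals[src]
    for name, values in cols.items():
        out[name] = values
    return out


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Epoched multichannel data with a key-based link to a trial table.

    Attributes
    ----------
    data
        ``(n_trials, n_channels, n_samples)`` float array.
    sampling_rate
        In Hz (100 after standard preprocessing).
    times
        Seconds relative to noise onset; strictly increasing, uniform at
        ``1/sampling_rate``.
    channel_labels
        One label per channel.
    trial_keys
        ``(n_trials, 2)`` array of ``(participant, trial_index)`` keys linking
        each epoch to a trial-table row.
    events
        Annotation name -> onset in seconds (e.g. ``{"tone": 1.0, "cue": 1.25}``).
    """

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    channel_labels: list[str]
    trial_keys: np.ndarray
    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.trial_keys = np.asarray(self.trial_keys)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise IntegrityError("data must be trials x channels x samples")
        n, c, s = self.data.shape
        if len(self.times) != s:
            raise IntegrityError("times length must match the sample axis")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
            raise IntegrityError("times must be uniform at 1/sampling_rate")
        if len(dt) and np.any(dt <= 0):
            raise IntegrityError("times must be strictly increasing")
        if not np.isfinite(self.data).all():
            raise IntegrityError("epoch data contain non-finite values")
        if len(self.channel_labels) != c:
            raise IntegrityError("channel_labels length must match channel axis")
        if self.trial_keys.shape != (n, 2):
            raise IntegrityError("trial_keys must be (n_trials, 2)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def key_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trial_keys, columns=["participant", "trial_index"])

    def subset(self, mask: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to ``mask`` (bool or index array)."""
        return EpochSet(
            data=self.data[mask],
            sampling_rate=self.sampling_rate,
            times=self.times,
            channel_labels=list(self.channel_labels),
            trial_keys=self.trial_keys[mask],
            events=dict(self.events),
        )

    def align_to(self, trials: pd.DataFrame) -> "EpochSet":
        """Keep only epochs whose key appears in ``trials`` (in table order)."""
        keys = list(zip(trials["participant"].tolist(), trials["trial_index"].tolist()))
        lookup = {tuple(k): i for i, k in enumerate(map(tuple, self.trial_keys.tolist()))}
        missing = [k for k in keys if k not in lookup]
        if missing:
            raise IntegrityError(
                f"{len(missing)} trial rows have no matching epoch, e.g. {missing[:5]}"
            )
        order = np.array([lookup[k] for k in keys], dtype=int)
        return self.subset(order)

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds)."""
        return int(np.argmin(np.abs(self.times - t)))


def save_epochs(epochs: EpochSet, base_path: str | Path) -> None:
    """Write ``<base>.npy`` + ``<base>.meta.json`` (normative dialect)."""
    base = Path(base_path)
    base = base.with_suffix("") if base.suffix == ".npy" else base
    np.save(base.with_suffix(".npy"), epochs.data)
    meta = {
        "sampling_rate": float(epochs.sampling_rate),
        "times": epochs.times.tolist(),
        "channel_labels": list(epochs.channel_labels),
        "events": {k: float(v) for k, v in epochs.events.items()},
        "trial_keys": [[p, int(t)] for p, t in epochs.trial_keys.tolist()],
    }
    with open(str(base) + ".meta.json", "w") as fh:
        json.dump(meta, fh)


def load_epochs(base_path: str | Path) -> EpochSet:
    """Read the ``.npy`` + ``.meta.json`` pair written by :func:`save_epochs`."""
    base = Path(base_path)
    base = base.with_suffix("") if base.suffix == ".npy" else base
    data = np.load(base.with_suffix(".npy"))
    with open(str(base) + ".meta.json") as fh:
        meta = json.load(fh)
    keys = np.array(meta["trial_keys"], dtype=object)
    if len(keys) != data.shape[0]:
        raise IntegrityError(
            f"metadata lists {len(keys)} trials but array holds {data.shape[0]}"
        )
    return EpochSet(
        data=data,
        sampling_rate=meta["sampling_rate"],
        times=np.array(meta["times"]),
        channel_labels=meta["channel_labels"],
        trial_keys=keys,
        events=meta.get("events", {}),
    )


def to_mne(epochs: EpochSet):
    """Convert to :class:`mne.EpochsArray` (convenience adapter)."""
    import mne

    info = mne.create_info(
        [str(c) for c in epochs.channel_labels], epochs.sampling_rate, ch_types="eeg"
    )
    return mne.EpochsArray(
        epochs.data, info, tmin=float(epochs.times[0]), verbose="error"
    )


def from_mne(mne_epochs, trial_keys: np.ndarray, events: dict | None = None) -> EpochSet:
    """Build an :class:`EpochSet` from an MNE epochs object plus trial keys."""
    return EpochSet(
        data=mne_epochs.get_data(copy=True),
        sampling_rate=float(mne_epochs.info["sfreq"]),
        times=mne_epochs.times.copy(),
        channel_labels=list(mne_epochs.ch_names),
        trial_keys=np.asarray(trial_keys),
        events=dict(events or {}),
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _rt_outlier_mask(trials: pd.DataFrame, k: float, scope: str) -> np.ndarray:
    """True where reaction time exceeds mean + k*SD (SD=0 removes nothing)."""
    rt = trials["reaction_time"].to_numpy(dtype=float)
    out = np.zeros(len(trials), dtype=bool)
    if scope == "pooled":
        groups = [np.arange(len(trials))]
    else:
        groups = [idx for _, idx in trials.groupby("participant", sort=False).indices.items()]
    for idx in groups:
        mu = rt[idx].mean()
        sd = rt[idx].std(ddof=1) if len(idx) > 1 else 0.0
        if sd > 0:
            out[idx] = rt[idx] > mu + k * sd
    return out


def apply_filters(
    trials: pd.DataFrame,
    epochs: EpochSet | None,
    spec: FilterSpec,
) -> tuple[pd.DataFrame, EpochSet | None]:
    """Apply exclusion rules, re-derive history with chain breaks, subset epochs.

    Order of operations: validity flag -> per-participant RT rule -> history
    re-derivation (removed trials leave their neighbors with undefined
    history) -> previous-pitch-level exclusion -> final history re-derivation.
    """
    out = trials.copy()
    if spec.require_valid and "valid" in out.columns:
        out = out[out["valid"].astype(bool)]
    if spec.rt_sd_threshold is not None:
        if "reaction_time" not in out.columns:
            raise SchemaError("RT filtering requested but reaction_time column missing")
        drop = _rt_outlier_mask(out, spec.rt_sd_threshold, spec.rt_scope)
        out = out[~drop]
    out = derive_history_columns(out, -1)
    out = derive_history_columns(out, +1)
    if spec.exclude_prev_levels:
        keep = ~out["prev_pitch"].isin(list(spec.exclude_prev_levels))
        out = out[keep]
        out = derive_history_columns(out, -1)
        out = derive_history_columns(out, +1)
    out = out.reset_index(drop=True)

    counts = out.groupby("participant", sort=False).size() if len(out) else pd.Series(dtype=int)
    lost = set(trials["participant"].unique()) - set(counts.index)
    if lost:
        warnings.warn(f"filtering removed all trials for participants {sorted(lost)}")

    if epochs is not None:
        epochs = epochs.align_to(out)
    return out, epochs
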