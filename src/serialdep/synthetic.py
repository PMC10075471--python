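"""Generative model for serial-bias experiments: behavior and epoched signals.

Behavior follows a hierarchical Bernoulli-logit choice model: participant
``i``'s per-trial probability of reporting "high" is

    p_ij = logistic(b0_i + b1_i * CurrentPitch + b2_i * PrevPitch
                    + b3_i * PrevCategory),     beta_i = gamma + mu_i,
    mu_i ~ N(0, Sigma)

with pitch levels 1..5 mapped to a centered covariate (default −2..+2) and
previous category coded ±0.5.  Pitch sequences are pseudorandomized in
balanced blocks (equal counts per level within each block).  Motor responses
are tied to the categorical choice through a response-cue mapping; the cue
sequence can be biased so that the motor response switches sides with a
planted probability, planting a motor serial bias that is independent of the
choice process.

Epochs superimpose, per trial and feature (pitch / category / motor), a
feature-specific channel template modulated by a smooth activation envelope
locked to the tone or the response cue.  Three planted manipulations emulate
the phenomena the analysis stack is built to detect:

- *activation*: the current feature's template, amplitude ``amplitude``;
- *reactivation*: the previous trial's template re-expressed during the
  current activation window, amplitude ``reactivation_gain``;
- *representational shift*: the current template morphed along the chord
  toward (λ > 0, attraction) or away from (λ < 0, repulsion) the previous
  trial's template: ``(1−|λ|)·T(cur) + λ·T(prev)``.

Noise is spatially correlated Gaussian (exponential channel-distance kernel)
with optional AR(1) temporal smoothing.  Everything is reproducible from the
seed: the same seed yields bitwise-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from serialdep.io import EpochSet, derive_history_columns

logger = logging.getLogger(__name__)

#: Default mapping of pitch level -> centered numeric covariate.
DEFAULT_PITCH_CODING = {1: -2.0, 2: -1.0, 3: 0.0, 4: 1.0, 5: 2.0}


def code_pitch(levels, coding: Mapping[int, float] | None = None) -> np.ndarray:
    """Map pitch levels 1..5 to the centered numeric covariate."""
    coding = DEFAULT_PITCH_CODING if coding is None else coding
    return np.asarray([coding[int(v)] for v in np.asarray(levels)], dtype=float)


def code_category(choices) -> np.ndarray:
    """Map binary choices {0,1} to the centered covariate {−0.5, +0.5}."""
    return np.asarray(choices, dtype=float) - 0.5


@dataclass
class SynthBehaviorConfig:
    """Ground-truth parameters for the behavioral generator.

    ``gamma`` holds the group-level coefficients (intercept, current pitch,
    previous pitch, previous category) on the logit scale with the covariate
    codings above; ``Sigma`` the 4x4 between-participant covariance of the
    per-participant deviations.  ``switch_prob`` is the probability that the
    response-cue sequence makes the motor response switch sides relative to
    the previous trial (0.5 = unbiased).
    """

    n_participants: int = 30
    n_trials: int = 2000
    gamma: tuple[float, float, float, float] = (0.0, 1.2, -0.8, 1.7)
    Sigma: np.ndarray | None = None
    pitch_coding: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_PITCH_CODING))
    switch_prob: float = 0.5
    block_size: int = 100
    rt_mean: float = 0.55
    rt_sd: float = 0.12
    rt_outlier_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Sigma is None:
            # modest inter-individual spread (SDs 0.3, 0.2, 0.2, 0.3)
            self.Sigma = np.diag([0.09, 0.04, 0.04, 0.09])
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (4, 4):
            raise ValueError("Sigma must be 4x4")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        if np.linalg.eigvalsh(self.Sigma).min() < -1e-10:
            raise ValueError("Sigma must be positive semidefinite")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")
        if self.block_size % 5 != 0:
            raise ValueError("block_size must be a multiple of 5")
        if self.n_trials % self.block_size != 0:
            raise ValueError("n_trials must be a multiple of block_size")


def _balanced_pitch_sequence(n_trials: int, block_size: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudorandom pitch levels: equal counts of 1..5 shuffled per block."""
    per = block_size // 5
    blocks = []
    for _ in range(n_trials // block_size):
        block = np.repeat(np.arange(1, 6), per)
        rng.shuffle(block)
        blocks.append(block)
    return np.concatenate(blocks)


def simulate_behavior(cfg: SynthBehaviorConfig) -> pd.DataFrame:
    """Draw a trial table from the hierarchical choice model.

    First-trial history terms use a cold start of 0 (the neutral value of the
    centered codings); fitting routines drop those rows instead.  Returns a
    validated trial table with ``prev_*``/``next_*`` columns derived and a
    boolean ``rt_outlier`` column marking planted reaction-time outliers.
    """
    rng = np.random.default_rng(cfg.seed)
    gamma = np.asarray(cfg.gamma, dtype=float)
    # eigh-based root handles PSD (including singular) covariances
    evals, evecs = np.linalg.eigh(cfg.Sigma)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    frames = []
    for i in range(cfg.n_participants):
        beta = gamma + root @ rng.standard_normal(4)
        pitch = _balanced_pitch_sequence(cfg.n_trials, cfg.block_size, rng)
        x_cur = code_pitch(pitch, cfg.pitch_coding)

        choice = np.zeros(cfg.n_trials, dtype=int)
        motor = np.zeros(cfg.n_trials, dtype=int)
        mapping = np.zeros(cfg.n_trials, dtype=int)
        u_choice = rng.random(cfg.n_trials)
        u_switch = rng.random(cfg.n_trials)
        u_map0 = rng.integers(0, 2)
        for j in range(cfg.n_trials):
            prev_pitch_term = x_cur[j - 1] if j > 0 else 0.0
            prev_cat_term = (choice[j - 1] - 0.5) if j > 0 else 0.0
            eta = (
                beta[0]
                + beta[1] * x_cur[j]
                + beta[2] * prev_pitch_term
                + beta[3] * prev_cat_term
            )
            choice[j] = int(u_choice[j] < 1.0 / (1.0 + np.exp(-eta)))
            if j == 0:
                mapping[j] = u_map0
            else:
                want_switch = u_switch[j] < cfg.switch_prob
                desired = 1 - motor[j - 1] if want_switch else motor[j - 1]
                mapping[j] = desired ^ choice[j]
            motor[j] = choice[j] ^ mapping[j]

        rt = rng.normal(cfg.rt_mean, cfg.rt_sd, cfg.n_trials)
        rt = np.clip(rt, 0.15, None)
        outlier = np.zeros(cfg.n_trials, dtype=bool)
        if cfg.rt_outlier_frac > 0:
            n_out = int(round(cfg.rt_outlier_frac * cfg.n_trials))
            idx = rng.choice(cfg.n_trials, size=n_out, replace=False)
            rt[idx] = rt.mean() + 10.0 * rt.std(ddof=1)
            outlier[idx] = True

        frames.append(
            pd.DataFrame(
                {
                    "participant": f"P{i + 1:02d}",
                    "block": np.arange(cfg.n_trials) // cfg.block_size + 1,
                    "trial_index": np.arange(cfg.n_trials),
                    "pitch_level": pitch,
                    "choice": choice,
                    "motor_response": motor,
                    "cue_mapping": mapping,
                    "reaction_time": rt,
                    "valid": True,
                    "rt_outlier": outlier,
                }
            )
        )
    trials = pd.concat(frames, ignore_index=True)
    trials = derive_history_columns(trials, -1)
    trials = derive_history_columns(trials, +1)
    return trials


# ---------------------------------------------------------------------------
# Neural templates and epochs
# ---------------------------------------------------------------------------


@dataclass
class TemplateSet:
    """Unit-norm channel patterns, one per condition level."""

    patterns: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.patterns = {int(k): np.asarray(v, dtype=float) for k, v in self.patterns.items()}

    @property
    def levels(self) -> list[int]:
        return sorted(self.patterns)

    def matrix(self) -> np.ndarray:
        return np.stack([self.patterns[c] for c in self.levels])

    def gram(self) -> np.ndarray:
        m = self.matrix()
        return m @ m.T

    def min_pairwise_angle(self) -> float:
        """Smallest pairwise angle between patterns, in radians."""
        g = np.abs(self.gram())
        np.fill_diagonal(g, 0.0)
        return float(np.arccos(np.clip(g.max(), -1.0, 1.0)))


def make_condition_templates(
    n_channels: int, levels: int, seed: int | np.random.Generator = 0
) -> TemplateSet:
    """Reproducible pseudo-orthogonal unit-norm channel patterns.

    For ``levels <= n_channels`` the patterns are exactly orthonormal (QR of a
    seeded Gaussian matrix, signs fixed for reproducibility); otherwise they
    are merely normalized and a warning notes the degraded separation.
    """
    if levels < 2:
        raise ValueError("need at least 2 condition levels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = rng.standard_normal((n_channels, levels))
    if levels <= n_channels:
        q, r = np.linalg.qr(raw)
        q = q * np.sign(np.diag(r))
        patterns = {lev + 1: q[:, lev].copy() for lev in range(levels)}
    else:
        warnings.warn(
            f"{levels} levels exceed {n_channels} channels; template separation degrades"
        )
        patterns = {
            lev + 1: raw[:, lev] / np.linalg.norm(raw[:, lev]) for lev in range(levels)
        }
    return TemplateSet(patterns)


@dataclass
class FeatureSpec:
    """Planted dynamics of one feature (pitch, category, or motor response).

    ``lock`` names the event annotation the envelope is locked to; ``onset``
    and ``duration`` (seconds) position a cosine-ramped trapezoid activation
    envelope (rise/fall times in seconds) relative to that event.  ``shift_lambda`` in (−1, 1) morphs the current
    template toward (+) or away from (−) the previous trial's template;
    ``reactivation_gain`` re-expresses the previous template inside the
    current activation window.
    """

    column: str
    prev_column: str
    n_levels: int
    lock: str = "tone"
    onset: float = 0.08
    duration: float = 0.8
    rise: float = 0.05
    fall: float = 0.15
    amplitude: float = 1.0
    reactivation_gain: float = 0.0
    shift_lambda: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.shift_lambda) < 1.0:
            raise ValueError("|shift_lambda| must be < 1")
        if self.reactivation_gain < 0:
            raise ValueError("reactivation_gain must be >= 0")
        if self.rise + self.fall > self.duration:
            raise ValueError("rise + fall must not exceed duration")


def default_features(
    reactivation_gain: float = 0.0, shift_lambda: float = 0.0
) -> dict[str, FeatureSpec]:
    """Feature layout of the standard paradigm (tone at 1.0 s, cue at 1.25 s).

    Pitch and category activations are tone-locked, the motor activation is
    cue-locked; the scalars apply the same reactivation gain / shift to all
    three features (tests usually override per feature).
    """
    return {
        "pitch": FeatureSpec(
            column="pitch_level", prev_column="prev_pitch", n_levels=5,
            lock="tone", onset=0.08, duration=0.9,
            reactivation_gain=reactivation_gain, shift_lambda=shift_lambda,
        ),
        "category": FeatureSpec(
            column="choice", prev_column="prev_choice", n_levels=2,
            lock="tone", onset=0.15, duration=0.8,
            reactivation_gain=reactivation_gain, shift_lambda=shift_lambda,
        ),
        "motor": FeatureSpec(
            column="motor_response", prev_column="prev_motor", n_levels=2,
            lock="cue", onset=0.05, duration=0.7,
            reactivation_gain=reactivation_gain, shift_lambda=shift_lambda,
        ),
    }


@dataclass
class SynthNeuralConfig:
    """Planted structure for the epoch generator.

    Noise is Gaussian with an exponential-decay spatial covariance
    (``exp(-d/noise_lengthscale)`` over channel index distance ``d``),
    amplitude ``noise_amplitude`` (per-channel SD), optionally smoothed in
    time by an AR(1) filter with coefficient ``noise_ar`` (variance
    renormalized).  Templates are unit-norm, so per-trial discriminability at
    the envelope peak is roughly ``amplitude * sqrt(2) / noise_amplitude``.
    """

    n_channels: int = 64
    sampling_rate: float = 100.0
    t_start: float = 0.0
    t_stop: float = 2.25
    events: dict[str, float] = field(default_factory=lambda: {"tone": 1.0, "cue": 1.25})
    features: dict[str, FeatureSpec] = field(default_factory=default_features)
    noise_amplitude: float = 2.0
    noise_lengthscale: float = 5.0
    noise_ar: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if np.linalg.eigvalsh(self.spatial_covariance()).min() <= 0:
            raise ValueError("noise spatial covariance must be SPD")
        for name, fs in self.features.items():
            if fs.lock not in self.events:
                raise ValueError(f"feature {name!r} locks to unknown event {fs.lock!r}")
            t0 = self.events[fs.lock] + fs.onset
            if t0 < self.t_start or t0 + fs.duration > self.t_stop:
                raise ValueError(f"feature {name!r} envelope exceeds the epoch window")

    def spatial_covariance(self) -> np.ndarray:
        idx = np.arange(self.n_channels)
        return np.exp(-np.abs(idx[:, None] - idx[None, :]) / self.noise_lengthscale)

    def times(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) * self.sampling_rate)) + 1
        return self.t_start + np.arange(n) / self.sampling_rate


def _activation_envelope(
    times: np.ndarray, t0: float, duration: float, rise: float, fall: float
) -> np.ndarray:
    """Cosine-ramped trapezoid: sharp, well-defined onset with a smooth decay."""
    env = np.zeros_like(times)
    rel = times - t0
    inside = (rel >= 0) & (rel <= duration)
    r = rel[inside]
    e = np.ones_like(r)
    if rise > 0:
        up = r < rise
        e[up] = np.sin(0.5 * np.pi * r[up] / rise) ** 2
    if fall > 0:
        down = r > duration - fall
        e[down] = np.sin(0.5 * np.pi * (duration - r[down]) / fall) ** 2
    env[inside] = e
    return env


def make_feature_templates(cfg: SynthNeuralConfig) -> dict[str, TemplateSet]:
    """One TemplateSet per feature, all drawn from the config seed.

    All features share one QR basis, so templates are mutually orthogonal
    across features as well as within (no cross-feature pattern leakage).
    """
    total = sum(fs.n_levels for fs in cfg.features.values())
    basis = make_condition_templates(cfg.n_channels, max(total, 2), seed=cfg.seed)
    out: dict[str, TemplateSet] = {}
    k = 0
    for name, fs in cfg.features.items():
        out[name] = TemplateSet(
            {lev: basis.patterns[k + lev] for lev in range(1, fs.n_levels + 1)}
        )
        k += fs.n_levels
    return out


def _feature_levels(values: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Map raw column values to template levels 1..n (binary 0/1 -> 1/2)."""
    vals = np.asarray(values, dtype=float)
    if spec.n_levels == 2:
        return np.where(np.isnan(vals), np.nan, vals + 1)
    return vals


def simulate_epochs(
    trials: pd.DataFrame,
    cfg: SynthNeuralConfig,
    templates: dict[str, TemplateSet] | None = None,
) -> EpochSet:
    """Generate one epoch per trial row with planted feature structure.

    ``trials`` must carry derived history columns.  Trials with undefined
    history receive neither the reactivation nor the shift term for the
    affected feature (their count is logged).
    """
    for fs in cfg.features.values():
        if fs.prev_column not in trials.columns:
            raise ValueError(f"trials lack history column {fs.prev_column!r}")
    rng = np.random.default_rng(cfg.seed)
    if templates is None:
        templates = make_feature_templates(cfg)
    times = cfg.times()
    n_trials, n_ch, n_s = len(trials), cfg.n_channels, len(times)

    data = np.zeros((n_trials, n_ch, n_s))
    n_skipped = 0
    for name, fs in cfg.features.items():
        tset = templates[name]
        env = _activation_envelope(
            times, cfg.events[fs.lock] + fs.onset, fs.duration, fs.rise, fs.fall
        )
        cur = _feature_levels(trials[fs.column].to_numpy(), fs)
        prev = _feature_levels(trials[fs.prev_column].to_numpy(), fs)
        # one channel pattern per (current, previous) combination
        combos: dict[tuple[float, float], np.ndarray] = {}
        pattern_rows = np.zeros((n_trials, n_ch))
        for t in range(n_trials):
            key = (cur[t], prev[t] if np.isfinite(prev[t]) else np.nan)
            if key not in combos:
                t_cur = tset.patterns[int(key[0])]
                if np.isnan(key[1]):
                    pat = fs.amplitude * t_cur
                else:
                    t_prev = tset.patterns[int(key[1])]
                    lam = fs.shift_lambda
                    morph = (1.0 - abs(lam)) * t_cur + lam * t_prev
                    pat = fs.amplitude * morph + fs.reactivation_gain * t_prev
                combos[key] = pat
            pattern_rows[t] = combos[key]
        if fs.reactivation_gain > 0:
            n_skipped += int(np.isnan(prev).sum())
        data += pattern_rows[:, :, None] * env[None, None, :]
    if n_skipped:
        logger.info("reactivation term skipped for %d trials with undefined history", n_skipped)

    noise = rng.standard_normal((n_trials, n_ch, n_s))
    if cfg.noise_ar:
        a = cfg.noise_ar
        from scipy.signal import lfilter

        noise = lfilter([np.sqrt(1.0 - a * a)], [1.0, -a], noise, axis=-1)
    chol = np.linalg.cholesky(cfg.spatial_covariance())
    noise = np.einsum("cd,tds->tcs", chol, noise)
    data += cfg.noise_amplitude * noise

    keys = np.empty((n_trials, 2), dtype=object)
    keys[:, 0] = trials["participant"].to_numpy()
    keys[:, 1] = trials["trial_index"].to_numpy()
    return EpochSet(
        data=data,
        sampling_rate=cfg.sampling_rate,
        times=times,
        channel_labels=[f"CH{c + 1:02d}" for c in range(n_ch)],
        trial_keys=keys,
        events=dict(cfg.events),
    )


def with_feature(
    cfg: SynthNeuralConfig, name: str, **overrides
) -> SynthNeuralConfig:
    """Return a config with one feature's parameters replaced (convenience)."""
    feats = dict(cfg.features)
    feats[name] = replace(feats[name], **overrides)
    return replace(cfg, features=feats)
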