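"""Behavioral serial-bias analyses.

Covers the aggregate psychometric curves, the four mixed-effects logistic
models of choice history (Model 1: current pitch only; Model 2: + previous
pitch; Model 3: + previous category; Model 4: both), AIC model comparison,
the distance-resolved category bias with permutation/bootstrap inference, the
motor switch/stay bias, and per-participant bias indices with the High/Low
bias median split.

All four models are fitted on the same observation set (rows with defined
previous-trial history), so their AICs are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from serialdep.glmm import GLMMResult, fit_binomial_glmm, logistic_irls
from serialdep.synthetic import code_category, code_pitch

#: Predictors per model (intercept implicit first).
MODEL_TERMS = {
    1: ["current_pitch"],
    2: ["current_pitch", "prev_pitch"],
    3: ["current_pitch", "prev_category"],
    4: ["current_pitch", "prev_pitch", "prev_category"],
}


@dataclass
class GLMMFit:
    """One fitted serial-bias model with reporting-ready fixed effects."""

    model_id: int
    fixed_effects: pd.DataFrame  # estimate, se, ci_low, ci_high, z, p per term
    random_cov: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    result: GLMMResult

    def coef(self, name: str) -> float:
        return float(self.fixed_effects.loc[name, "estimate"])

    def participant_coefficients(self) -> pd.DataFrame:
        """Per-participant coefficients (fixed effect + BLUP deviation)."""
        return pd.DataFrame(
            self.result.blups["coefficients"],
            index=pd.Index(self.result.blups["labels"], name="participant"),
            columns=self.fixed_effects.index,
        )


def _design(trials: pd.DataFrame, model_id: int, pitch_coding=None):
    """History-complete rows -> (X, y, groups, names) for the given model."""
    if model_id not in MODEL_TERMS:
        raise ValueError(f"model_id must be 1..4, got {model_id}")
    needed = ["prev_pitch", "prev_choice"]
    for col in needed:
        if col not in trials.columns:
            raise ValueError(f"trials lack history column {col!r}")
    rows = trials.dropna(subset=needed)
    cols = {
        "intercept": np.ones(len(rows)),
        "current_pitch": code_pitch(rows["pitch_level"], pitch_coding),
        "prev_pitch": code_pitch(rows["prev_pitch"].astype(int), pitch_coding),
        "prev_category": code_category(rows["prev_choice"]),
    }
    names = ["intercept"] + MODEL_TERMS[model_id]
    X = np.column_stack([cols[c] for c in names])
    y = rows["choice"].to_numpy(dtype=float)
    groups = rows["participant"].to_numpy()
    return X, y, groups, names


def fit_serial_glmm(
    trials: pd.DataFrame,
    model_id: int,
    pitch_coding: dict[int, float] | None = None,
    max_outer: int = 200,
) -> GLMMFit:
    """Fit one of Models 1-4 (binomial logit, correlated random slopes)."""
    X, y, groups, names = _design(trials, model_id, pitch_coding)
    res = fit_binomial_glmm(X, y, groups, param_names=names, max_outer=max_outer)
    if not res.converged:
        warnings.warn(
            f"model {model_id} optimizer did not report convergence "
            f"(max |gradient| = {res.gradient_norm:.3g})"
        )
    ci = res.ci
    z = res.zvalues
    fe = pd.DataFrame(
        {
            "estimate": res.gamma,
            "se": res.se,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(names, name="term"),
    )
    return GLMMFit(
        model_id=model_id,
        fixed_effects=fe,
        random_cov=res.Sigma,
        loglik=res.loglik,
        aic=res.aic,
        n_obs=res.n_obs,
        n_params=res.n_params,
        converged=res.converged,
        result=res,
    )


def compare_models(fits: list[GLMMFit]) -> pd.DataFrame:
    """ΔAIC of each model against Model 1; smaller AIC wins.

    Refuses to compare fits on different observation sets.
    """
    by_id = {f.model_id: f for f in fits}
    if 1 not in by_id:
        raise ValueError("compare_models requires Model 1 as the reference")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"AIC not comparable: fits use different n_obs {sorted(n_obs)}")
    ref = by_id[1].aic
    rows = []
    best = min(fits, key=lambda f: f.aic)
    for f in sorted(fits, key=lambda f: f.model_id):
        rows.append(
            {
                "model_id": f.model_id,
                "aic": f.aic,
                "delta_aic": f.aic - ref,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "winner": f.model_id == best.model_id,
            }
        )
    return pd.DataFrame(rows).set_index("model_id")


# ---------------------------------------------------------------------------
# Aggregate curves and pointwise logistic fits
# ---------------------------------------------------------------------------


def aggregate_choice_curves(trials: pd.DataFrame, condition_on: str) -> pd.DataFrame:
    """Percent-"high" per (conditioning level x current pitch), aggregated.

    ``condition_on`` is ``"prev_pitch"`` or ``"prev_choice"``.  Rows with
    undefined history are dropped.  Cells absent from the data appear with
    ``n = 0`` and undefined percent (``empty`` flag set).
    """
    if condition_on not in ("prev_pitch", "prev_choice"):
        raise ValueError("condition_on must be 'prev_pitch' or 'prev_choice'")
    rows = trials.dropna(subset=[condition_on])
    grp = rows.groupby([condition_on, "pitch_level"])["choice"]
    table = grp.agg(n="size", n_high="sum").reset_index()
    cond_levels = sorted(rows[condition_on].unique())
    full = pd.MultiIndex.from_product(
        [cond_levels, [1, 2, 3, 4, 5]], names=[condition_on, "pitch_level"]
    )
    table = (
        table.set_index([condition_on, "pitch_level"])
        .reindex(full)
        .fillna({"n": 0, "n_high": 0})
        .reset_index()
    )
    table["n"] = table["n"].astype(int)
    table["n_high"] = table["n_high"].astype(int)
    with np.errstate(invalid="ignore"):
        table["p_high"] = np.where(table["n"] > 0, table["n_high"] / table["n"], np.nan)
    table["empty"] = table["n"] == 0
    return table


@dataclass
class PointwiseLogisticFit:
    """Binomial logistic fit of percent-high on pitch level."""

    intercept: float
    slope: float
    separation_flagged: bool

    def predict(self, levels) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(levels, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def inverse(self, percents) -> np.ndarray:
        """Pitch level at which the fitted curve crosses each percent."""
        p = np.asarray(percents, dtype=float)
        return (np.log(p / (1.0 - p)) - self.intercept) / self.slope


def fit_pointwise_logistic(levels, successes, totals) -> PointwiseLogisticFit:
    """Maximum-likelihood logistic fit to binomial counts per pitch level.

    Complete separation is detected and handled by a lightly penalized
    (ridge) refit, flagged on the result.
    """
    import statsmodels.api as sm

    levels = np.asarray(levels, dtype=float)
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("totals must be positive")
    X = sm.add_constant(levels)
    endog = np.column_stack([successes, totals - successes])
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=100)
            intercept, slope = fit.params
            props = successes / totals
            separated = np.all((props == 0) | (props == 1)) and len(set(props)) > 1
            if not np.isfinite([intercept, slope]).all() or abs(slope) > 25 or separated:
                raise ValueError("separation")
        except Exception:
            flagged = True
            # ridge fallback on expanded Bernoulli representation
            reps = totals.astype(int)
            Xe = np.column_stack([np.ones(reps.sum()), np.repeat(levels, reps)])
            ye = np.concatenate(
                [
                    np.r_[np.ones(int(s)), np.zeros(int(t - s))]
                    for s, t in zip(successes, totals)
                ]
            )
            beta, _ = logistic_irls(Xe, ye, ridge=1e-2)
            intercept, slope = beta
    return PointwiseLogisticFit(float(intercept), float(slope), flagged)


# ---------------------------------------------------------------------------
# Distance-modulated category bias
# ---------------------------------------------------------------------------


def _cell_effects(cur, prevp, prevc, y) -> np.ndarray:
    """Per (prev_pitch, cur_pitch) cell: P(high | prev high) − P(high | prev low)."""
    idx = ((prevp - 1) * 5 + (cur - 1)) * 2 + prevc
    n = np.bincount(idx, minlength=50).astype(float)
    s = np.bincount(idx, weights=y, minlength=50)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, s / n, np.nan)
    p = p.reshape(25, 2)
    return p[:, 1] - p[:, 0]


def _distance_average(effects: np.ndarray) -> np.ndarray:
    """Average the 25 cell effects by |current − previous| pitch distance."""
    prevp, cur = np.divmod(np.arange(25), 5)
    dist = np.abs(cur - prevp)
    out = np.full(5, np.nan)
    for d in range(5):
        cells = effects[dist == d]
        if np.isfinite(cells).any():
            out[d] = np.nanmean(cells)
    return out


def category_bias_by_distance(
    trials: pd.DataFrame,
    n_perm: int = 5000,
    n_boot: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Previous-choice effect on percent-high, by previous-current pitch distance.

    The effect at distance d averages, over all (previous pitch, current
    pitch) cells with ``|difference| = d``, the difference in percent-high
    between trials preceded by a "high" versus a "low" choice (aggregated
    over participants).  Significance comes from shuffling the trial-history
    assignment within participant; CIs from a trial-level bootstrap.
    """
    rows = trials.dropna(subset=["prev_pitch", "prev_choice"])
    cur = rows["pitch_level"].to_numpy(dtype=int)
    prevp = rows["prev_pitch"].to_numpy(dtype=int)
    prevc = rows["prev_choice"].to_numpy(dtype=int)
    y = rows["choice"].to_numpy(dtype=float)
    part = rows["participant"].to_numpy()

    obs = _distance_average(_cell_effects(cur, prevp, prevc, y))

    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(part == lab) for lab in pd.unique(part)]
    null = np.empty((n_perm, 5))
    for r in range(n_perm):
        pp = prevp.copy()
        pc = prevc.copy()
        for idx in groups:
            order = rng.permutation(len(idx))
            pp[idx] = pp[idx][order]
            pc[idx] = pc[idx][order]
        null[r] = _distance_average(_cell_effects(cur, pp, pc, y))
    with np.errstate(invalid="ignore"):
        pvals = (1.0 + np.nansum(np.abs(null) >= np.abs(obs), axis=0)) / (n_perm + 1.0)

    boot = np.empty((n_boot, 5))
    n = len(rows)
    for r in range(n_boot):
        take = rng.integers(0, n, n)
        boot[r] = _distance_average(
            _cell_effects(cur[take], prevp[take], prevc[take], y[take])
        )
    ci = np.nanpercentile(boot, [2.5, 97.5], axis=0)

    return pd.DataFrame(
        {
            "distance": np.arange(5),
            "effect": obs,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": np.where(np.isfinite(obs), pvals, np.nan),
        }
    )


# ---------------------------------------------------------------------------
# Motor switch/stay bias and per-participant indices
# ---------------------------------------------------------------------------


def motor_switch_bias(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-participant switch/stay rates plus the group paired comparison.

    Switch = motor response differs from the previous trial; rates sum to 1
    by construction.  The group test is a paired t test of switch vs stay.
    """
    rows = trials.dropna(subset=["prev_motor"])
    per = (
        rows.assign(switch=(rows["motor_response"] != rows["prev_motor"]).astype(float))
        .groupby("participant", sort=False)["switch"]
        .mean()
        .rename("switch_rate")
        .to_frame()
    )
    per["stay_rate"] = 1.0 - per["switch_rate"]
    if len(per) >= 2:
        t, p = stats.ttest_rel(per["switch_rate"], per["stay_rate"])
        test = {"t": float(t), "p": float(p), "df": len(per) - 1}
    else:
        test = {"t": np.nan, "p": np.nan, "df": 0}
    return per, test


@dataclass
class BiasIndices:
    """Per-participant serial-bias indices.

    ``pitch_bias`` and ``category_bias`` are Model-4 previous-pitch /
    previous-category coefficients (BLUP or per-participant GLM, see
    ``method``); ``motor_bias`` is switch rate − stay rate (in [−1, 1]).
    """

    table: pd.DataFrame
    method: str


def bias_indices(
    trials: pd.DataFrame,
    model4: GLMMFit | None = None,
    method: str = "blup",
) -> BiasIndices:
    """Compute the three per-participant bias indices.

    ``method="blup"`` (default) uses Model-4 conditional modes;
    ``method="perglm"`` fits an independent logistic regression per
    participant instead.
    """
    if method not in ("blup", "perglm"):
        raise ValueError("method must be 'blup' or 'perglm'")
    if method == "blup":
        if model4 is None:
            model4 = fit_serial_glmm(trials, 4)
        if model4.model_id != 4:
            raise ValueError("bias indices require Model 4")
        coefs = model4.participant_coefficients()
        tab = coefs[["prev_pitch", "prev_category"]].rename(
            columns={"prev_pitch": "pitch_bias", "prev_category": "category_bias"}
        )
    else:
        X, y, groups, names = _design(trials, 4)
        recs = {}
        for lab in pd.unique(groups):
            m = groups == lab
            beta, _ = logistic_irls(X[m], y[m], ridge=1e-4)
            recs[lab] = beta
        tab = pd.DataFrame.from_dict(recs, orient="index", columns=names)
        tab.index.name = "participant"
        tab = tab[["prev_pitch", "prev_category"]].rename(
            columns={"prev_pitch": "pitch_bias", "prev_category": "category_bias"}
        )
    per, _ = motor_switch_bias(trials)
    motor = (per["switch_rate"] - per["stay_rate"]).rename("motor_bias")
    tab = tab.join(motor, how="left")
    return BiasIndices(table=tab, method=method)


#: Behavioral direction of "stronger bias" per feature: pitch bias is
#: repulsive (more negative = stronger), category attraction and motor
#: switch bias are positive-going.
BIAS_DIRECTION = {"pitch": -1.0, "category": +1.0, "motor": +1.0}


def split_bias_groups(
    indices: BiasIndices, feature: str, direction: float | None = None
) -> pd.Series:
    """Equal-size High/Low-bias median split for one feature.

    The signed index is oriented by the feature's group-level bias direction
    so that "High" always means *more biased*.  Ties at the median are broken
    deterministically by participant id (stable sort).
    """
    if feature not in BIAS_DIRECTION:
        raise ValueError(f"feature must be one of {sorted(BIAS_DIRECTION)}")
    direction = BIAS_DIRECTION[feature] if direction is None else direction
    col = f"{feature}_bias"
    tab = indices.table.sort_index()
    oriented = tab[col] * direction
    order = oriented.sort_values(ascending=False, kind="stable").index
    n_high = len(order) // 2
    labels = pd.Series("Low", index=tab.index, name=f"{feature}_group")
    labels.loc[order[:n_high]] = "High"
    return labels
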