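"""Maximum-likelihood binomial-logit mixed models via the Laplace approximation.

Fits models of the form

    y_ij ~ Bernoulli(logistic(x_ij' beta_i)),   beta_i = gamma + mu_i,
    mu_i ~ N(0, Sigma)

where every fixed effect also has a participant-level random slope and Sigma
is a full (correlated) covariance.  The marginal likelihood is integrated
over the random effects with a per-participant Laplace approximation — the
same strategy as lme4's default — which is essentially exact here because
cluster sizes are in the hundreds to thousands.

Parameterization: Sigma = L L' with L lower-triangular, diagonal on the log
scale.  The outer optimization (L-BFGS-B over gamma and L) uses
finite-difference gradients; inner random-effect modes are found by Newton
iterations warm-started across outer evaluations.

Fixed-effect standard errors use the standard GLMM information
(sum_i X_i' V_i^{-1} X_i)^{-1} with V_i = W_i^{-1} + X_i Sigma X_i',
evaluated at the conditional modes and reduced to p x p form with the
Woodbury identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

_LOGDIAG_MIN = -6.0  # lower bound on log-scale RE standard deviations


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logistic_irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-6, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Plain logistic regression; returns (coef, covariance).

    A tiny ridge keeps separation-prone small samples finite.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        g = X.T @ (y - mu) - ridge * beta
        H = (X.T * w) @ X + ridge * np.eye(p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    eta = X @ beta
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * w) @ X + ridge * np.eye(p))
    return beta, cov


def _theta_split(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """theta -> (gamma, L) with L lower-triangular, log-diagonal."""
    gamma = theta[:p]
    L = np.zeros((p, p))
    L[np.diag_indices(p)] = np.exp(theta[p : 2 * p])
    if p > 1:
        L[np.tril_indices(p, -1)] = theta[2 * p :]
    return gamma, L


def _theta_join(gamma: np.ndarray, L: np.ndarray) -> np.ndarray:
    p = len(gamma)
    parts = [gamma, np.log(np.clip(np.diag(L), np.exp(_LOGDIAG_MIN), None))]
    if p > 1:
        parts.append(L[np.tril_indices(p, -1)])
    return np.concatenate(parts)


@dataclass
class GLMMResult:
    """Laplace-ML fit of the hierarchical logistic model."""

    param_names: list[str]
    gamma: np.ndarray
    se: np.ndarray
    Sigma: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    n_params: int
    converged: bool
    gradient_norm: float
    blups: dict[str, np.ndarray] = field(default_factory=dict)
    singular: bool = False

    @property
    def zvalues(self) -> np.ndarray:
        return self.gamma / self.se

    @property
    def ci(self) -> np.ndarray:
        """95% Wald intervals, rows (low, high)."""
        half = 1.959963984540054 * self.se
        return np.stack([self.gamma - half, self.gamma + half], axis=1)


class _LaplaceObjective:
    """Negative Laplace log-likelihood, vectorized over participants.

    Groups are padded to a common length with zero-weight rows so that all
    inner Newton iterations run as stacked einsum/solve operations; modes are
    warm-started across outer evaluations.
    """

    def __init__(self, Xs: list[np.ndarray], ys: list[np.ndarray]):
        self.G = len(Xs)
        self.p = Xs[0].shape[1]
        N = max(len(y) for y in ys)
        self.X = np.zeros((self.G, N, self.p))
        self.y = np.zeros((self.G, N))
        self.m = np.zeros((self.G, N))
        for i, (Xi, yi) in enumerate(zip(Xs, ys)):
            self.X[i, : len(yi)] = Xi
            self.y[i, : len(yi)] = yi
            self.m[i, : len(yi)] = 1.0
        self.modes = np.zeros((self.G, self.p))

    def _f(self, offset, A, U):
        eta = offset + (A @ U[:, :, None])[:, :, 0]
        ll = (self.m * (self.y * eta - np.logaddexp(0.0, eta))).sum(axis=1)
        return ll - 0.5 * (U * U).sum(axis=1), eta

    @staticmethod
    def _hessian(A, w, eye):
        return A.transpose(0, 2, 1) @ (A * w[:, :, None]) + eye

    def nll(self, theta: np.ndarray) -> float:
        gamma, L = _theta_split(theta, self.p)
        A = self.X @ L
        offset = self.X @ gamma
        U = self.modes.copy()
        eye = np.eye(self.p)
        fu, eta = self._f(offset, A, U)
        for _ in range(60):
            mu = _sigmoid(eta)
            w = self.m * mu * (1.0 - mu)
            resid = self.m * (self.y - mu)
            g = (A.transpose(0, 2, 1) @ resid[:, :, None])[:, :, 0] - U
            if np.abs(g).max() < 1e-9:
                break
            H = self._hessian(A, w, eye)
            step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
            # vectorized step-halving for the rare non-improving groups
            t = np.ones(self.G)
            for _ in range(30):
                U_new = U + t[:, None] * step
                f_new, eta_new = self._f(offset, A, U_new)
                bad = f_new < fu - 1e-12
                if not bad.any():
                    break
                t[bad] *= 0.5
            U, fu, eta = U_new, np.maximum(f_new, fu), eta_new
        self.modes = U
        mu = _sigmoid(eta)
        w = self.m * mu * (1.0 - mu)
        H = self._hessian(A, w, eye)
        _, logdet = np.linalg.slogdet(H)
        return -float((fu - 0.5 * logdet).sum())


def fit_binomial_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    param_names: list[str] | None = None,
    max_outer: int = 200,
) -> GLMMResult:
    """Fit the random-slopes binomial GLMM by Laplace ML.

    Parameters
    ----------
    X
        ``(n, p)`` design matrix (first column typically the intercept); the
        random-effect design equals the fixed-effect design.
    y
        Binary responses.
    groups
        Participant labels, one per row.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if param_names is None:
        param_names = [f"x{j}" for j in range(p)]
    labels = pd.unique(groups)
    Xs, ys = [], []
    for lab in labels:
        m = groups == lab
        Xs.append(X[m])
        ys.append(y[m])

    # --- initialization from per-participant GLMs
    betas = np.zeros((len(Xs), p))
    covs = np.zeros((len(Xs), p, p))
    for i, (Xi, yi) in enumerate(zip(Xs, ys)):
        betas[i], covs[i] = logistic_irls(Xi, yi, ridge=1e-3)
    gamma0 = betas.mean(axis=0)
    between = np.cov(betas.T) if len(Xs) > 1 else np.eye(p) * 0.01
    between = np.atleast_2d(between) - covs.mean(axis=0)
    evals, evecs = np.linalg.eigh((between + between.T) / 2.0)
    Sigma0 = (evecs * np.clip(evals, 1e-4, None)) @ evecs.T
    L0 = np.linalg.cholesky(Sigma0)

    obj = _LaplaceObjective(Xs, ys)
    theta0 = _theta_join(gamma0, L0)
    bounds = (
        [(None, None)] * p
        + [(_LOGDIAG_MIN, 3.0)] * p
        + [(None, None)] * (p * (p - 1) // 2)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            obj.nll,
            theta0,
            method="L-BFGS-B",
            jac=None,
            bounds=bounds,
            options={"maxiter": max_outer, "ftol": 1e-9, "gtol": 1e-3, "eps": 1e-5},
        )
    gamma, L = _theta_split(res.x, p)
    Sigma = L @ L.T
    loglik = -obj.nll(res.x)  # also refreshes modes at the optimum

    singular = bool(np.any(np.log(np.diag(L)) < _LOGDIAG_MIN + 1.0))
    if singular:
        warnings.warn(
            "random-effect covariance near-singular; consider a simpler RE structure"
        )

    # --- fixed-effect covariance via Woodbury-reduced GLMM information
    info = np.zeros((p, p))
    blup_u = np.zeros((len(Xs), p))
    for i, (Xi, yi) in enumerate(zip(Xs, ys)):
        u = obj.modes[i]
        blup_u[i] = u
        eta = Xi @ gamma + (Xi @ L) @ u
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        XtWX = (Xi.T * w) @ Xi
        B = XtWX @ L
        inner = np.eye(p) + L.T @ XtWX @ L
        info += XtWX - B @ np.linalg.solve(inner, B.T)
    se = np.sqrt(np.diag(np.linalg.inv(info)))

    k = p + p * (p + 1) // 2
    blups = {
        "labels": np.asarray(labels),
        "deviations": blup_u @ L.T,
        "coefficients": gamma[None, :] + blup_u @ L.T,
    }
    grad_norm = float(np.abs(res.jac).max()) if res.jac is not None else np.nan
    return GLMMResult(
        param_names=list(param_names),
        gamma=gamma,
        se=se,
        Sigma=Sigma,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        n_obs=n,
        n_groups=len(Xs),
        n_params=k,
        converged=bool(res.success),
        gradient_norm=grad_norm,
        blups=blups,
        singular=singular,
    )
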