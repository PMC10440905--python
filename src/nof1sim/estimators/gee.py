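"""Generalized estimating equations for a logistic marginal model.

Solves the GEE score equations sum_i D_i' V_i^{-1} (y_i - mu_i) = 0 for a
logit link with clusters = patients, under an *independence* or *AR1*
working correlation.  With the logit link D_i = A_i X_i and
V_i = A_i^{1/2} R A_i^{1/2} (A = diag(mu(1-mu))), so each Fisher-scoring
step only needs R^{-1} applied to vectors; for AR1 the inverse working
correlation is tridiagonal and is applied in closed form.  The AR1
parameter is estimated between steps as the lag-1 autocorrelation of the
Pearson residuals within patients (adjacent retained observations are
treated as consecutive).  Under independence the solution coincides with
the ordinary logistic-regression MLE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError, EstimationError

CORSTRS = ("independence", "ar1")
_ALPHA_MAX = 0.95
_ETA_MAX = 30.0


def _cluster_slices(groups: np.ndarray) -> list[slice]:
    """Contiguous slices per cluster; rows must be grouped (sorted by cluster)."""
    change = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    bounds = np.r_[change, len(groups)]
    if len(np.unique(groups)) != len(change):
        raise ConfigError("rows of one cluster must be contiguous (sort by patient, day)")
    return [slice(s, e) for s, e in zip(bounds[:-1], bounds[1:])]


def _ar1_inverse_apply(u: np.ndarray, alpha: float, slices) -> np.ndarray:
    """R^{-1} u for the AR1 working correlation, applied per cluster.

    The inverse of an AR1 correlation matrix is tridiagonal:
    (R^{-1} u)_t = [ (1 + a^2) u_t - a (u_{t-1} + u_{t+1}) ] / (1 - a^2)
    with the coefficient 1 instead of 1 + a^2 at both ends.
    """
    if alpha == 0.0:
        return u
    out = np.empty_like(u)
    denom = 1.0 - alpha * alpha
    for sl in slices:
        v = u[sl]
        m = len(v)
        if m == 1:
            out[sl] = v
            continue
        w = (1.0 + alpha * alpha) * v
        w[0] = v[0]
        w[-1] = v[-1]
        w[1:] -= alpha * v[:-1]
        w[:-1] -= alpha * v[1:]
        out[sl] = w / denom
    return out


def _lag1_autocorr(r: np.ndarray, slices) -> float:
    """Lag-1 autocorrelation of residuals pooled over within-cluster pairs."""
    num = 0.0
    for sl in slices:
        v = r[sl]
        if len(v) > 1:
            num += float(v[:-1] @ v[1:])
    den = float(r @ r)
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, -_ALPHA_MAX, _ALPHA_MAX))


@dataclass
class GeeFit:
    """Solved GEE coefficients for the logistic propensity model."""

    params: np.ndarray
    names: list[str]
    corstr: str
    ar1_param: float | None
    n_iter: int
    converged: bool

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.names.index(name)])


def fit_gee_logistic(response, design, groups, corstr: str = "independence",
                     names=None, tol: float = 1e-9, max_iter: int = 200,
                     beta_start=None) -> GeeFit:
    """Solve the logistic GEE for ``response`` on ``design`` clustered by ``groups``."""
    if corstr not in CORSTRS:
        raise ConfigError(f"unknown working correlation {corstr!r}; choose from {CORSTRS}")
    y = np.asarray(response, dtype=float).ravel()
    if isinstance(design, pd.DataFrame):
        names = list(design.columns) if names is None else list(names)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])] if names is None else list(names)
    groups = np.asarray(groups)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigError("response must be binary 0/1")
    slices = _cluster_slices(groups)
    n, p = X.shape
    beta = np.zeros(p) if beta_start is None else np.asarray(beta_start, dtype=float).copy()
    if np.any(np.abs(X @ beta) > _ETA_MAX):
        beta = np.zeros(p)  # unusable warm start
    alpha = 0.0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = mu * (1.0 - mu)
        sqv = np.sqrt(v)
        if corstr == "ar1":
            alpha = _lag1_autocorr((y - mu) / np.maximum(sqv, 1e-12), slices)
        # score: X' A^{1/2} R^{-1} A^{-1/2} (y - mu)
        score = X.T @ (sqv * _ar1_inverse_apply((y - mu) / np.maximum(sqv, 1e-12),
                                                alpha, slices))
        # information: X' A^{1/2} R^{-1} A^{1/2} X
        SX = sqv[:, None] * X
        RSX = np.column_stack([_ar1_inverse_apply(SX[:, j], alpha, slices)
                               for j in range(p)])
        info = SX.T @ RSX
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular GEE information matrix") from exc
        # step-halving keeps the linear predictor in a numerically safe range;
        # persistent boundary pressure indicates (quasi-)separation
        halvings = 0
        while np.any(np.abs(X @ (beta + step)) > _ETA_MAX) and halvings < 12:
            step = 0.5 * step
            halvings += 1
        if halvings >= 12:
            raise EstimationError(
                "logistic GEE diverged (possible separation in the propensity model)")
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return GeeFit(beta, names, corstr,
                          alpha if corstr == "ar1" else None, it, True)
    raise EstimationError(
        f"GEE did not converge in {max_iter} iterations "
        f"(last max step {np.max(np.abs(step)):.3g})")


class GeeLogistic:
    """Model wrapper: logistic GEE of a binary response on a design matrix."""

    def __init__(self, response, design, groups, corstr: str = "independence"):
        self.response = response
        self.design = design
        self.groups = groups
        self.corstr = corstr

    def fit(self, **kwargs) -> GeeFit:
        return fit_gee_logistic(self.response, self.design, self.groups,
                                corstr=self.corstr, **kwargs)
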