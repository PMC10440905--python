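"""Carry-over adjusted parametric model (COAPM).

The binary treatment indicators are replaced by continuous exponential-decay
exposure regressors E_1^t(tau_1, gamma_1) and E_2^t(tau_2, gamma_2):

    O^t = b0 + b1 E_1^t + b2 E_2^t + sum_j b3j C_j^t + e

The wash-in/wash-out parameters are unknown and selected by maximizing the
OLS R^2 over a grid.  Exposures are computed per patient over the *full*
treatment schedule: the assignment is a design quantity known even on days
with missing measurements, so the recursion evolves through missing days
while only complete-case rows enter the fit (toggleable).

Because the covariate block is the same at every grid point, each candidate
fit reduces -- after projecting outcome and exposure columns off the fixed
block (Frisch-Waugh) -- to a 2x2 solve, which makes the full joint grid over
(tau_1, gamma_1, tau_2, gamma_2) inexpensive.  A coordinate-wise search over
the two per-treatment grids is available as an alternative.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ..errors import ConfigError, EstimationError
from ..utils import check_full_rank
from .base import (
    BaseResults, DEFAULT_COVARIATES, OUTCOME, as_frame, available_covariates,
    treatment2_indicator,
)

_SINGULAR_REL = 1e-9


def _exposure_columns(df: pd.DataFrame, k: int, combos) -> np.ndarray:
    """Exposure columns E_k for every (tau, gamma) combo, rows aligned to ``df``.

    ``df`` must be sorted by patient and day and contain every scheduled day
    (including masked ones); E_k^0 = 0 at each patient's first day.
    """
    taus = np.array([c[0] for c in combos], dtype=float)
    gammas = np.array([c[1] for c in combos], dtype=float)
    on = (df["treatment"].to_numpy() == k).astype(float)
    out = np.empty((len(df), len(combos)))
    bounds = np.flatnonzero(np.r_[True, df["patient_id"].to_numpy()[1:]
                                  != df["patient_id"].to_numpy()[:-1]])
    bounds = np.r_[bounds, len(df)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        state = np.zeros(len(combos))
        for t in range(s, e):
            state = state + (1.0 - state) / taus * on[t] - state / gammas * (1.0 - on[t])
            out[t] = state
    return out


def coapm_design(data, tau1: float, gamma1: float, tau2: float, gamma2: float,
                 covariates=None) -> pd.DataFrame:
    """Regression-ready table with exposure columns ``e1``/``e2`` at fixed (tau, gamma).

    Masked days are excluded from the returned rows but not from the
    exposure recursion.
    """
    for v in (tau1, gamma1, tau2, gamma2):
        if v < 1:
            raise ConfigError("tau and gamma must be >= 1")
    df = as_frame(data).sort_values(["patient_id", "day"], kind="stable")
    covs = available_covariates(
        df, DEFAULT_COVARIATES if covariates is None else list(covariates))
    e1 = _exposure_columns(df, 1, [(tau1, gamma1)])[:, 0]
    e2 = _exposure_columns(df, 2, [(tau2, gamma2)])[:, 0]
    out = df[["patient_id", "day", "treatment", OUTCOME] + covs].copy()
    out.insert(3, "e1", e1)
    out.insert(4, "e2", e2)
    keep = ~df["missing"].astype(bool).to_numpy() if "missing" in df.columns \
        else np.ones(len(df), bool)
    out = out[keep].dropna(subset=[OUTCOME] + covs)
    return out.reset_index(drop=True)


class COAPM:
    """Model object for the carry-over adjusted parametric model.

    Parameters
    ----------
    data : Cohort, DataFrame or list of per-patient frames
    covariates : covariate columns (default: direct parents of the outcome)
    grid : iterable of candidate integer values for every tau_k and gamma_k
        (default 1..10)
    search : "joint" exhausts the full 4-parameter grid; "coordinate"
        alternates 2-D searches over each treatment's (tau_k, gamma_k)
        holding the other fixed, up to ``max_sweeps`` sweeps
    evolve_through_missing : keep the exposure recursion running over masked
        days (the schedule is known by design); if False the recursion only
        sees retained days
    """

    def __init__(self, data, covariates=None, grid=None, search: str = "joint",
                 max_sweeps: int = 5, evolve_through_missing: bool = True):
        if search not in ("joint", "coordinate"):
            raise ConfigError(f"unknown search mode {search!r}")
        grid = list(grid) if grid is not None else list(range(1, 11))
        if not grid or any(g < 1 for g in grid):
            raise ConfigError("grid values must be >= 1 and non-empty")
        self.grid = sorted(grid)
        self.search = search
        self.max_sweeps = max_sweeps
        df = as_frame(data).sort_values(["patient_id", "day"], kind="stable")
        self.covariates = available_covariates(
            df, DEFAULT_COVARIATES if covariates is None else list(covariates))
        if not evolve_through_missing and "missing" in df.columns:
            df = df[~df["missing"].astype(bool)]
        self.df_full = df.reset_index(drop=True)
        treatment2_indicator(self.df_full)  # label check
        keep = ~self.df_full["missing"].astype(bool).to_numpy() \
            if "missing" in self.df_full.columns else np.ones(len(self.df_full), bool)
        keep &= ~self.df_full[[OUTCOME] + self.covariates].isna().any(axis=1).to_numpy()
        self.cc_rows = keep

    # -- grid search -------------------------------------------------------

    def fit(self) -> "COAPMResults":
        combos = list(product(self.grid, self.grid))  # lexicographic (tau, gamma)
        df, cc = self.df_full, self.cc_rows
        if cc.sum() == 0:
            raise EstimationError("no complete-case rows to fit")
        y = df.loc[cc, OUTCOME].to_numpy(dtype=float)
        X0 = np.column_stack(
            [np.ones(cc.sum())] + [df.loc[cc, c].to_numpy(dtype=float)
                                   for c in self.covariates])
        check_full_rank(X0, ["const"] + self.covariates)
        Q, _ = np.linalg.qr(X0)

        def residualize(M):
            return M - Q @ (Q.T @ M)

        E1 = _exposure_columns(df, 1, combos)[cc]
        E2 = _exposure_columns(df, 2, combos)[cc]
        yt = residualize(y)
        E1t = residualize(E1)
        E2t = residualize(E2)
        a11 = np.einsum("ij,ij->j", E1t, E1t)
        a22 = np.einsum("ij,ij->j", E2t, E2t)
        b1 = E1t.T @ yt
        b2 = E2t.T @ yt
        A12 = E1t.T @ E2t
        yty = float(yt @ yt)
        sst = float(((y - y.mean()) ** 2).sum())
        # SSRs within float noise of the minimum are ties, resolved toward the
        # lexicographically smallest (tau1, gamma1, tau2, gamma2)
        tie_tol = 1e-9 * max(sst, np.finfo(float).tiny)

        def cell_ssr(i, j):
            det = a11[i] * a22[j] - A12[i, j] ** 2
            if det > _SINGULAR_REL * max(a11[i] * a22[j], np.finfo(float).tiny):
                beta1 = (a22[j] * b1[i] - A12[i, j] * b2[j]) / det
                beta2 = (a11[i] * b2[j] - A12[i, j] * b1[i]) / det
                return yty - beta1 * b1[i] - beta2 * b2[j], False
            if a11[i] > 0:  # E2 aliased with [X0, E1]: drop it (beta2 := 0)
                return yty - b1[i] ** 2 / a11[i], True
            return yty, True

        if self.search == "joint":
            det = np.outer(a11, a22) - A12 ** 2
            singular = det <= _SINGULAR_REL * np.maximum(
                np.outer(a11, a22), np.finfo(float).tiny)
            with np.errstate(divide="ignore", invalid="ignore"):
                beta1 = (a22[None, :] * b1[:, None] - A12 * b2[None, :]) / det
                beta2 = (a11[:, None] * b2[None, :] - A12 * b1[:, None]) / det
                ssr = yty - beta1 * b1[:, None] - beta2 * b2[None, :]
                ssr_aliased = np.where(a11 > 0, yty - b1 ** 2 / np.where(a11 > 0, a11, 1.0),
                                       yty)
            ssr = np.where(singular, ssr_aliased[:, None], ssr)
            # first index in row-major order within the tie band = smallest
            # (tau1, gamma1, tau2, gamma2)
            flat = int(np.argmax(ssr.ravel() <= ssr.min() + tie_tol))
            i_sel, j_sel = np.unravel_index(flat, ssr.shape)
            n_fits = ssr.size
        else:
            def sweep(fixed, along_first):
                best_idx, best_ssr = 0, np.inf
                for idx in range(len(combos)):
                    s = cell_ssr(idx, fixed)[0] if along_first \
                        else cell_ssr(fixed, idx)[0]
                    if s < best_ssr - tie_tol:
                        best_idx, best_ssr = idx, s
                return best_idx

            i_sel = j_sel = 0
            n_fits = 0
            for _ in range(self.max_sweeps):
                prev = (i_sel, j_sel)
                i_sel = sweep(j_sel, along_first=True)
                j_sel = sweep(i_sel, along_first=False)
                n_fits += 2 * len(combos)
                if (i_sel, j_sel) == prev:
                    break
        ssr_sel, aliased = cell_ssr(i_sel, j_sel)
        tau1, gamma1 = combos[i_sel]
        tau2, gamma2 = combos[j_sel]
        return self._refit(tau1, gamma1, tau2, gamma2, aliased, sst, n_fits)

    def _refit(self, tau1, gamma1, tau2, gamma2, aliased, sst, n_fits):
        """OLS at the selected grid point; coefficients and SEs come from here."""
        df, cc = self.df_full, self.cc_rows
        e1 = _exposure_columns(df, 1, [(tau1, gamma1)])[cc, 0]
        e2 = _exposure_columns(df, 2, [(tau2, gamma2)])[cc, 0]
        X = pd.DataFrame({"const": 1.0, "e1": e1}, index=np.arange(cc.sum()))
        if not aliased:
            X["e2"] = e2
        for c in self.covariates:
            X[c] = df.loc[cc, c].to_numpy(dtype=float)
        res = sm.OLS(df.loc[cc, OUTCOME].to_numpy(dtype=float), X).fit()
        return COAPMResults(res, (tau1, gamma1, tau2, gamma2), aliased, n_fits)


class COAPMResults(BaseResults):
    """Selected-model fit: exposure coefficients, (tau, gamma) and R^2.

    ``beta1``/``beta2`` estimate the carry-over adjusted effect of each
    treatment versus no treatment; their difference beta1 - beta2 is the
    reported treatment effect difference (truth +2 under the default
    generating effects).  When the two exposure columns are aliased (e.g.
    tau = gamma = 1 for both treatments makes E1 + E2 constant), the second
    column is dropped and beta1 is directly the between-treatment contrast.
    """

    method = "coapm"

    def __init__(self, ols_results, selected, aliased, n_fits):
        self.ols_results = ols_results
        self.tau1, self.gamma1, self.tau2, self.gamma2 = (float(v) for v in selected)
        self.aliased = bool(aliased)
        self.n_fits = int(n_fits)
        self.params = ols_results.params

    @property
    def beta1(self) -> float:
        return float(self.params["e1"])

    @property
    def beta2(self) -> float:
        return 0.0 if self.aliased else float(self.params["e2"])

    @property
    def se_beta1(self) -> float:
        return float(self.ols_results.bse["e1"])

    @property
    def se_beta2(self) -> float | None:
        return None if self.aliased else float(self.ols_results.bse["e2"])

    @property
    def r_squared(self) -> float:
        return float(self.ols_results.rsquared)

    @property
    def effect_difference(self) -> float:
        return self.beta1 - self.beta2

    @property
    def se(self) -> float:
        if self.aliased:
            return self.se_beta1
        cov = self.ols_results.cov_params()
        v = cov.loc["e1", "e1"] + cov.loc["e2", "e2"] - 2 * cov.loc["e1", "e2"]
        return float(np.sqrt(max(v, 0.0)))

    def _extra(self):
        return {
            "beta1": self.beta1, "beta2": self.beta2,
            "tau1": self.tau1, "gamma1": self.gamma1,
            "tau2": self.tau2, "gamma2": self.gamma2,
            "r_squared": self.r_squared, "aliased": self.aliased,
        }
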