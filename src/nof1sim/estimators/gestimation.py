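"""G-estimation of the average treatment effect difference in a structural
nested mean model.

The design has no untreated days, so the binary treatment contrast T is
coded 1 = treatment 2 and 0 = treatment 1; the structural parameter psi is
then directly the average effect difference beta_2 - beta_1 of treatment 2
versus treatment 1.  For a candidate psi the residualized outcome
H(psi) = O - psi * T is entered into the logistic propensity model

    logit P(T = 1 | H, C) = theta_0 + theta_1 H(psi) + sum_j theta_2j C_j

fitted by GEE (independence or AR1 working correlation) with patients as
clusters.  Under conditional exchangeability theta_1 = 0 at the true psi, so
psi_hat is the root of theta_1(psi), found by Brent's method over a
bracketing interval (with a grid fallback when no sign change is found).
The reported effect difference is -psi_hat, matching the package-wide
orientation E[O | T1] - E[O | T2].
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from ..errors import BracketingError, EstimationError
from .base import (
    BaseResults, GEST_COVARIATES, OUTCOME, as_frame, available_covariates,
    complete_cases, treatment2_indicator,
)
from .gee import fit_gee_logistic


class GEstimation:
    """Model object for SNMM G-estimation with a GEE propensity model.

    Parameters
    ----------
    data : Cohort, DataFrame or list of per-patient frames
    covariates : propensity-model covariates (default: all observed
        covariates with a direct or indirect effect on the outcome)
    corstr : "independence" or "ar1" working correlation
    interval : search interval for psi, expected to bracket the root
    tol : acceptance tolerance on |theta_1| at the solution
    """

    def __init__(self, data, covariates=None, corstr: str = "independence",
                 interval: tuple[float, float] = (-10.0, 10.0), tol: float = 1e-4):
        df = as_frame(data).sort_values(["patient_id", "day"], kind="stable")
        self.covariates = available_covariates(
            df, GEST_COVARIATES if covariates is None else list(covariates))
        self.df = complete_cases(df, [OUTCOME] + self.covariates)
        self.corstr = corstr
        self.interval = (float(interval[0]), float(interval[1]))
        self.tol = float(tol)

    def fit(self) -> "GEstimationResults":
        df = self.df
        t2 = treatment2_indicator(df)
        y = df[OUTCOME].to_numpy(dtype=float)
        groups = df["patient_id"].to_numpy()
        C = np.column_stack([df[c].to_numpy(dtype=float) for c in self.covariates]) \
            if self.covariates else np.empty((len(df), 0))
        names = ["const", "h"] + self.covariates
        n_evals = 0
        last_beta = {"b": None}

        def theta1(psi: float) -> float:
            nonlocal n_evals
            h = y - psi * t2
            X = np.column_stack([np.ones(len(df)), h, C])
            n_evals += 1
            try:
                try:
                    fit = fit_gee_logistic(t2, X, groups, corstr=self.corstr,
                                           names=names, beta_start=last_beta["b"])
                except EstimationError:
                    # retry cold before concluding the model really separates
                    fit = fit_gee_logistic(t2, X, groups, corstr=self.corstr,
                                           names=names)
            except EstimationError:
                # far from the root H(psi) (quasi-)separates the groups and the
                # logistic fit diverges; the sign of theta_1 is still determined
                # by which group has the larger H, which is all bracketing needs
                last_beta["b"] = None
                theta1.last_fit = None
                return float(np.sign(h[t2 == 1].mean() - h[t2 == 0].mean()) * 1e6)
            last_beta["b"] = fit.params
            theta1.last_fit = fit
            return fit["h"]

        lo, hi = self.interval
        f_lo, f_hi = theta1(lo), theta1(hi)
        if f_lo * f_hi < 0:
            psi = brentq(theta1, lo, hi, xtol=1e-9)
        else:
            psi = self._grid_fallback(theta1, lo, hi)
        t1 = theta1(psi)
        if theta1.last_fit is None or abs(t1) > self.tol:
            raise EstimationError(
                f"|theta_1| = {abs(t1):.3g} at psi = {psi:.4f} exceeds the "
                f"tolerance {self.tol}")
        fit = theta1.last_fit
        return GEstimationResults(psi=float(psi), theta1=float(t1),
                                  corstr=self.corstr, ar1_param=fit.ar1_param,
                                  n_evals=n_evals, propensity_fit=fit)

    def _grid_fallback(self, theta1, lo: float, hi: float) -> float:
        """Coarse scan for a sign change, then Brent; else fine-grid argmin."""
        coarse = np.arange(lo, hi + 0.25, 0.5)
        vals = [theta1(p) for p in coarse]
        for (p0, f0), (p1, f1) in zip(zip(coarse, vals), zip(coarse[1:], vals[1:])):
            if f0 * f1 < 0:
                return brentq(theta1, p0, p1, xtol=1e-9)
        fine = np.arange(lo, hi + 0.005, 0.01)
        best = min(fine, key=lambda p: abs(theta1(p)))
        if abs(theta1(best)) > self.tol:
            raise BracketingError(
                f"theta_1(psi) has no sign change in [{lo}, {hi}]; "
                "widen the search interval")
        return float(best)


class GEstimationResults(BaseResults):
    """psi_hat with search diagnostics; SEs come from the Monte-Carlo layer."""

    def __init__(self, psi, theta1, corstr, ar1_param, n_evals, propensity_fit):
        self.psi = psi
        self.theta1 = theta1
        self.corstr = corstr
        self.ar1_param = ar1_param
        self.n_evals = n_evals
        self.propensity_fit = propensity_fit

    @property
    def method(self) -> str:  # type: ignore[override]
        return "gest_ind" if self.corstr == "independence" else "gest_ar1"

    @property
    def effect_difference(self) -> float:
        return -self.psi

    def _extra(self):
        extra = {"psi": self.psi, "theta1_at_solution": self.theta1,
                 "working_correlation": self.corstr, "n_evals": self.n_evals}
        if self.ar1_param is not None:
            extra["ar1_param"] = float(self.ar1_param)
        return extra
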