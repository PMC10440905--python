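"""Reference analyses: naive sample-mean contrast and covariate-adjusted OLS."""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ..errors import EstimationError
from ..utils import check_full_rank
from .base import (
    BaseResults, DEFAULT_COVARIATES, OUTCOME, as_frame, available_covariates,
    complete_cases, treatment2_indicator,
)


class SampleMeanContrast:
    """Naive estimator: difference of the two treatment groups' mean outcomes.

    The estimate is mean(outcome | treatment 1) - mean(outcome | treatment 2);
    no model-based standard error is produced (the Monte-Carlo layer supplies
    the empirical one).
    """

    def __init__(self, data):
        self.df = complete_cases(as_frame(data), [OUTCOME])

    def fit(self) -> "SampleMeanResults":
        t2 = treatment2_indicator(self.df)
        y = self.df[OUTCOME].to_numpy(dtype=float)
        n1, n2 = int((t2 == 0).sum()), int((t2 == 1).sum())
        if n1 == 0 or n2 == 0:
            raise EstimationError(
                f"a treatment group is empty after dropping masked days "
                f"(n1={n1}, n2={n2})"
            )
        return SampleMeanResults(
            estimate=float(y[t2 == 0].mean() - y[t2 == 1].mean()),
            group_means=(float(y[t2 == 0].mean()), float(y[t2 == 1].mean())),
            n_obs=(n1, n2),
        )


class SampleMeanResults(BaseResults):
    method = "sample_mean"

    def __init__(self, estimate, group_means, n_obs):
        self._estimate = estimate
        self.group_means = group_means
        self.n_obs = n_obs

    @property
    def effect_difference(self) -> float:
        return self._estimate

    def _extra(self):
        return {"mean_t1": self.group_means[0], "mean_t2": self.group_means[1]}


class TrialLinearModel:
    """Pooled multiple linear regression of the outcome on treatment + covariates.

    Ordinary least squares on the long table, treating patient-days as
    independent observations; the covariate set defaults to the variables
    with direct effects on the outcome.  The treatment enters as the
    indicator of treatment 2, so the reported effect difference is the
    negated treatment coefficient.
    """

    def __init__(self, data, covariates=None):
        df = as_frame(data)
        self.covariates = available_covariates(
            df, DEFAULT_COVARIATES if covariates is None else list(covariates))
        self.df = complete_cases(df, [OUTCOME] + self.covariates)

    def fit(self) -> "LinearModelResults":
        df = self.df
        X = pd.DataFrame({"const": np.ones(len(df)), "t2": treatment2_indicator(df)})
        for c in self.covariates:
            X[c] = df[c].to_numpy(dtype=float)
        check_full_rank(X.to_numpy(), list(X.columns))
        res = sm.OLS(df[OUTCOME].to_numpy(dtype=float), X).fit()
        return LinearModelResults(res)


class LinearModelResults(BaseResults):
    method = "lm"

    def __init__(self, ols_results):
        self.ols_results = ols_results
        self.params = ols_results.params

    @property
    def effect_difference(self) -> float:
        return -float(self.params["t2"])

    @property
    def se(self) -> float:
        return float(self.ols_results.bse["t2"])

    def _extra(self):
        return {"r_squared": float(self.ols_results.rsquared),
                "n_obs": int(self.ols_results.nobs)}

    def summary(self) -> str:
        return (super().summary() + "\n\n" + str(self.ols_results.summary()))
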