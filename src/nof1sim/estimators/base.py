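"""Shared estimator plumbing: data access, sign convention, result container.

Sign convention used by every estimator in the package: the reported
``effect_difference`` is E[outcome | treatment 1] - E[outcome | treatment 2],
so with generating effects -2 and -4 the truth is +2 (pain is lower under
treatment 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import EstimationError, SchemaError
from ..simulate import Cohort

#: Covariates with direct effects on the pain outcome (the direct parents of
#: pain in the default graph, excluding demographics).
DEFAULT_COVARIATES = [
    "activity", "stress", "sleep_quality", "medication",
    "prev_diagnosis", "chronic_diseases", "education", "work",
]

#: Covariate set for the propensity model of G-estimation: all observed
#: covariates with a direct or indirect effect on the outcome.
GEST_COVARIATES = DEFAULT_COVARIATES + ["demographics"]

OUTCOME = "pain"
TREATMENT = "treatment"


def as_frame(data) -> pd.DataFrame:
    """Extract the long-format table from a Cohort / DataFrame / list of frames."""
    if isinstance(data, Cohort):
        return data.data
    if isinstance(data, pd.DataFrame):
        return data
    if isinstance(data, (list, tuple)):
        return pd.concat(list(data), ignore_index=True)
    raise SchemaError(f"cannot interpret {type(data).__name__} as trial data")


def complete_cases(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Drop masked days and (listwise) rows with NA in the analysis columns."""
    if "missing" in df.columns:
        df = df[~df["missing"].astype(bool)]
    if columns is not None:
        cols = [c for c in columns if c in df.columns]
        df = df.dropna(subset=cols)
    return df


def available_covariates(df: pd.DataFrame, requested) -> list[str]:
    cols = [c for c in requested if c in df.columns]
    absent = [c for c in requested if c not in df.columns]
    if absent and not cols:
        raise SchemaError(f"none of the requested covariates are present: {requested}")
    return cols


def nondegenerate_covariates(df: pd.DataFrame, candidates) -> list[str]:
    """Candidates that actually vary among the complete-case rows.

    A covariate that is constant in a (small) sample is aliased with the
    intercept and carries no adjustment information; dropping it mirrors how
    R's ``lm`` marks such coefficients NA and proceeds.
    """
    sub = complete_cases(df, [c for c in candidates if c in df.columns])
    out = []
    for c in candidates:
        if c in sub.columns and sub[c].nunique(dropna=True) > 1:
            out.append(c)
    return out


def treatment2_indicator(df: pd.DataFrame) -> np.ndarray:
    """0/1 coding of the two-treatment variable (1 = treatment 2)."""
    t = df[TREATMENT].to_numpy()
    labels = set(np.unique(t).tolist())
    if not labels <= {1, 2}:
        raise SchemaError(f"treatment labels must be in {{1, 2}}, found {sorted(labels)}")
    return (t == 2).astype(float)


@dataclass
class EstimateResult:
    """A point estimate of the treatment effect difference with optional SE."""

    method: str
    estimate: float
    se: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se is not None and self.se < 0:
            raise EstimationError("standard error must be >= 0")

    def to_dict(self) -> dict:
        d = {"method": self.method, "estimate": float(self.estimate),
             "se": None if self.se is None else float(self.se)}
        d.update({k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                  for k, v in self.extra.items()})
        return d


class BaseResults:
    """Common surface of all fitted-model result objects."""

    method: str = ""

    @property
    def effect_difference(self) -> float:
        raise NotImplementedError

    @property
    def se(self) -> float | None:
        return None

    def to_estimate(self) -> EstimateResult:
        return EstimateResult(self.method, self.effect_difference, self.se,
                              extra=self._extra())

    def _extra(self) -> dict:
        return {}

    def summary(self) -> str:
        lines = [f"{self.__class__.__name__} (method={self.method})",
                 f"  effect difference (T1 - T2): {self.effect_difference: .4f}"]
        if self.se is not None:
            lines.append(f"  standard error:              {self.se: .4f}")
        for k, v in self._extra().items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines)
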