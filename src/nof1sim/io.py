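"""Tabular I/O: long-format trial CSVs, result files, run manifests.

CSV dialect: UTF-8, comma-separated, ``NA`` for missing cells, one row per
patient-day with columns ``patient_id, day, block, period, treatment,
<covariates...>, pain, missing``.  Masked days keep their keys and the
(design-known) treatment assignment; measurement cells are emitted as NA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import Cohort

MANDATORY_COLUMNS = ["patient_id", "day", "treatment", "pain"]
KEY_COLUMNS = ["patient_id", "day", "block", "period", "treatment"]


def read_trial_csv(path) -> Cohort:
    """Read a long-format trial table; rows are sorted within patient by day.

    Cells read as NA mark the row's measurements missing (row-wise mask);
    unknown columns are preserved as covariates.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    dup = df.duplicated(subset=["patient_id", "day"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["patient_id", "day"]].tolist()
        raise SchemaError(f"duplicate (patient, day) row: {tuple(pair)}")
    df = df.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)
    value_cols = [c for c in df.columns if c not in KEY_COLUMNS + ["missing"]]
    derived = df[value_cols].isna().any(axis=1)
    if "missing" in df.columns:
        df["missing"] = df["missing"].astype(bool) | derived
    else:
        df["missing"] = derived
    return Cohort(data=df)


def write_trial_csv(cohort: Cohort | pd.DataFrame, path, mask_columns=None) -> None:
    """Write a cohort; masked rows get NA in their measurement cells."""
    if isinstance(cohort, pd.DataFrame):
        cohort = Cohort(data=cohort)
    df = cohort.data.copy()
    if "missing" in df.columns and df["missing"].any():
        cols = mask_columns if mask_columns is not None else cohort.time_varying_columns()
        cols = [c for c in cols if c in df.columns]
        df.loc[df["missing"].astype(bool), cols] = np.nan
    df.to_csv(path, index=False, na_rep="NA")


def write_results(result, path) -> None:
    """JSON for single estimates, tidy CSV for Monte-Carlo tables."""
    from .montecarlo import ScenarioResultTable

    path = Path(path)
    if isinstance(result, ScenarioResultTable):
        result.to_csv(path)
        return
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
        return
    if hasattr(result, "to_estimate"):
        result = result.to_estimate()
    if hasattr(result, "to_dict"):
        payload = result.to_dict()
    elif isinstance(result, dict):
        payload = result
    else:
        raise SchemaError(f"cannot serialize result of type {type(result).__name__}")
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass
class RunManifest:
    """Provenance sidecar written next to every CLI output."""

    command: str
    seed: int | None
    config_hash: str
    version: str = ""
    argv: list[str] = None
    created: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if self.argv is None:
            self.argv = list(sys.argv)
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def config_hash(obj) -> str:
    """Stable sha256 of a configuration-like object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
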