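"""Tidy-CSV readers/writers for the pipeline's three table kinds.

Canonical column sets (one row per observation):

* labeling curve   — ``time_h, replicate, field, label, n_total, n_labeled``
* exit count table — ``replicate, field, marker, edu, ki67, count,
  pulse_h, chase_h``
* flow event table — ``reporter_intensity, viability_intensity, day,
  condition, role, replicate``
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ParameterError

LABELING_COLUMNS = ["time_h", "replicate", "field", "label", "n_total", "n_labeled"]
EXIT_COLUMNS = [
    "replicate", "field", "marker", "edu", "ki67", "count", "pulse_h", "chase_h",
]
FLOW_COLUMNS = [
    "reporter_intensity", "viability_intensity", "day", "condition", "role",
    "replicate",
]

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParameterError(f"{what} is missing columns {missing}")


def validate_labeling_curve(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, LABELING_COLUMNS, "labeling curve")
    if np.any(df["time_h"].to_numpy() <= 0):
        raise ParameterError("exposure times must be strictly positive")
    if np.any(df["n_labeled"].to_numpy() < 0) or np.any(
        df["n_labeled"].to_numpy() > df["n_total"].to_numpy()
    ):
        raise ParameterError("need 0 <= n_labeled <= n_total in every row")
    return df


def read_labeling_curve(path: PathLike) -> pd.DataFrame:
    return validate_labeling_curve(pd.read_csv(path))


def write_labeling_curve(df: pd.DataFrame, path: PathLike) -> None:
    validate_labeling_curve(df)[LABELING_COLUMNS].to_csv(path, index=False)


def validate_exit_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, EXIT_COLUMNS, "exit count table")
    if np.any(df["count"].to_numpy() < 0):
        raise ParameterError("counts must be >= 0")
    bad = set(df["edu"]).union(df["ki67"]) - {"pos", "neg"}
    if bad:
        raise ParameterError(f"edu/ki67 values must be 'pos'/'neg', got {bad}")
    return df


def read_exit_table(path: PathLike) -> pd.DataFrame:
    return validate_exit_table(pd.read_csv(path))


def write_exit_table(df: pd.DataFrame, path: PathLike) -> None:
    validate_exit_table(df)[EXIT_COLUMNS].to_csv(path, index=False)


def validate_flow_events(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, FLOW_COLUMNS, "flow event table")
    vals = df[["reporter_intensity", "viability_intensity"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise ParameterError("intensities must be finite and >= 0")
    return df


def read_flow_events(path: PathLike) -> pd.DataFrame:
    return validate_flow_events(pd.read_csv(path))


def write_flow_events(df: pd.DataFrame, path: PathLike) -> None:
    validate_flow_events(df)[FLOW_COLUMNS].to_csv(path, index=False)
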