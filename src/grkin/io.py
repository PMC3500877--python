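"""Delimited-text interchange: time-course tables, parameter files, fit reports.

The dataset schema is a flat CSV with columns
``gene, level {protein|mrna}, time_h, replicate, value_fold``;
validation reports 1-based file line numbers for malformed rows.
Parameter files are flat YAML maps of named rates (``dm_GR``, ``dp_GR``,
``k_act``, ``a_auto``, ``a_<src>_<tgt>``).  Fit reports are JSON.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .estimation import FitResult, TimeCourseDataset, REQUIRED_COLUMNS
from .models import PARAM_BOUNDS

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_params_file",
    "write_truth",
    "write_fit_report",
    "read_fit_report",
]

_PathLike = Union[str, Path]


def write_timecourse(dataset: TimeCourseDataset, path: _PathLike) -> None:
    """Write a dataset as CSV (full float precision, stable row order)."""
    df = dataset.frame[list(REQUIRED_COLUMNS)].sort_values(
        ["gene", "level", "time_h", "replicate"]).reset_index(drop=True)
    df.to_csv(path, index=False)


def read_timecourse(path: _PathLike) -> TimeCourseDataset:
    """Read and validate a time-course CSV; errors carry file line numbers."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: no data (empty file)")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data (header only)")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    messages = []
    # file line = dataframe index + 2 (1-based, header on line 1)
    for col, kind in (("time_h", float), ("value_fold", float), ("replicate", int)):
        coerced = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[coerced.isna()]:
            messages.append(f"line {i + 2}: {col}={df.at[i, col]!r} is not numeric")
        df[col] = coerced
    if not messages:
        for i in df.index[df["value_fold"] <= 0]:
            messages.append(f"line {i + 2}: value_fold={df.at[i, 'value_fold']} must be positive")
        for i in df.index[~df["level"].isin(["protein", "mrna"])]:
            messages.append(f"line {i + 2}: level={df.at[i, 'level']!r} must be protein|mrna")
        dup = df.duplicated(subset=["gene", "level", "time_h", "replicate"])
        for i in df.index[dup]:
            messages.append(f"line {i + 2}: duplicate (gene, level, time_h, replicate) key")
        at0 = df[(df["time_h"] == 0.0) & (np.abs(df["value_fold"] - 1.0) > 1e-9)]
        for i in at0.index:
            messages.append(f"line {i + 2}: value at t=0 must equal 1 (fold of control)")
    if messages:
        raise SchemaError([f"{path}: {m}" for m in messages])
    return TimeCourseDataset(df)


def read_params_file(path: _PathLike) -> Dict[str, float]:
    """Flat YAML map of named rates -> float."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping of rate name -> value")
    out = {}
    for k, v in raw.items():
        try:
            out[str(k)] = float(v)
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: rate {k!r} has non-numeric value {v!r}")
    return out


def write_truth(truth: Dict, path: _PathLike) -> None:
    """Structured record of a synthetic dataset's generating truth."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_fit_report(fit: FitResult, path: _PathLike) -> None:
    """Machine-readable fit report (JSON): parameters, residuals, provenance."""
    report = {
        "model_id": fit.model_id,
        "seed": fit.seed,
        "n_starts": fit.n_starts,
        "converged": fit.converged,
        "bounds": list(PARAM_BOUNDS),
        "stage1_params": fit.stage1_params,
        "stage2_params": fit.stage2_params,
        "epsilon_by_observable": {
            f"{g}.{l}": v for (g, l), v in sorted(fit.epsilon_by_observable.items())
        },
        "total_epsilon": fit.total_epsilon,
        "non_identifiable": list(fit.non_identifiable),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_report(path: _PathLike) -> Dict:
    with open(path) as fh:
        return json.load(fh)
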