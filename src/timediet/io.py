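"""CSV contracts for person-level cohort data.

One row per person; comma-separated, UTF-8, mandatory header, empty
cell = missing. Columns:

* seven raw daily durations (min/day) named as in
  :data:`timediet.compositional.TIME_USE_PARTS`, which must sum to 1440;
* ten diet items (``fruit_veg_1..3``, ``discretionary_1..4``,
  ``ssb_1..2``), integers 0-3;
* eight PedsQL items (``pedsql_1..8``), integers 0-4;
* covariates ``age`` (years), ``sex`` (0/1), ``sep`` (z-score).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .compositional import TIME_USE_PARTS, TOTAL_MINUTES
from .scoring import DIET_ITEM_COLUMNS, PEDSQL_ITEM_COLUMNS

DIET_ITEM_ALL = [c for cols in DIET_ITEM_COLUMNS.values() for c in cols]
COVARIATE_COLUMNS = ["age", "sex", "sep"]
COHORT_COLUMNS = (
    list(TIME_USE_PARTS) + DIET_ITEM_ALL + PEDSQL_ITEM_COLUMNS + COVARIATE_COLUMNS
)


def _check_items(df: pd.DataFrame, cols: list[str], low: int, high: int) -> None:
    for col in cols:
        v = df[col].to_numpy(dtype=float)
        bad = ~(np.isnan(v) | ((v >= low) & (v <= high) & (v == np.round(v))))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"invalid value {v[row]!r} in column {col!r}, row {row}: "
                f"expected integer in {low}..{high} or empty"
            )


def validate_cohort(df: pd.DataFrame) -> None:
    """Schema validation; raises ValueError naming row and column."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    _check_items(df, DIET_ITEM_ALL, 0, 3)
    _check_items(df, PEDSQL_ITEM_COLUMNS, 0, 4)
    dur = df[list(TIME_USE_PARTS)].to_numpy(dtype=float)
    complete = ~np.isnan(dur).any(axis=1)
    if np.any(dur[complete] < 0):
        r, c = np.argwhere((dur < 0) & complete[:, None])[0]
        raise ValueError(f"negative duration in column {TIME_USE_PARTS[c]!r}, row {r}")
    sums = dur[complete].sum(axis=1)
    bad = np.abs(sums - TOTAL_MINUTES) > 1e-6
    if bad.any():
        row = int(np.flatnonzero(complete)[np.flatnonzero(bad)[0]])
        raise ValueError(
            f"durations in row {row} sum to {sums[np.flatnonzero(bad)[0]]}, expected {TOTAL_MINUTES:g}"
        )


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a person-level cohort CSV."""
    df = pd.read_csv(path)
    validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV (missing values as empty cells)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def complete_case_filter(scored: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the analysis' complete-case flow, recording attrition.

    Order: valid time-use diary, complete diet scores, complete
    physical functioning, complete covariates. Returns the analytic
    sample and the sample size after each step.
    """
    attrition = {"provided": len(scored)}
    dur = scored[list(TIME_USE_PARTS)]
    ok = dur.notna().all(axis=1) & (np.abs(dur.sum(axis=1) - TOTAL_MINUTES) < 1e-6)
    out = scored[ok]
    attrition["valid_time_use"] = len(out)
    out = out.dropna(subset=["fruit_veg", "discretionary", "ssb"])
    attrition["complete_diet"] = len(out)
    out = out.dropna(subset=["pf_score"])
    attrition["complete_physical_functioning"] = len(out)
    out = out.dropna(subset=COVARIATE_COLUMNS)
    attrition["complete_covariates"] = len(out)
    return out.copy(), attrition
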