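"""CSV input/output and clinical-table preprocessing utilities."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .patterns import DataTable

logger = logging.getLogger("patternsub")

__all__ = [
    "load_clinical_csv",
    "write_table_csv",
    "mnary_shift",
    "dichotomize_at_median",
]


def load_clinical_csv(
    path,
    response: str,
    covariates: Sequence[str] | None = None,
    na_token: str = "NA",
    drop_missing_response: bool = True,
    drop_all_missing: bool = False,
) -> tuple[DataTable, dict[str, int]]:
    """Read a numeric table with a declared NA token.

    Returns the table plus exclusion counts.  Rows missing the response
    are dropped (and counted) by default; rows missing every covariate
    can optionally be dropped too.  A non-numeric cell that is not the
    NA token is an error naming its row and column.
    """
    df = pd.read_csv(path, na_values=[na_token], keep_default_na=False)
    cols = list(covariates) if covariates is not None else [c for c in df.columns if c != response]
    missing_cols = [c for c in [response, *cols] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path}: {missing_cols}")
    for c in [response, *cols]:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell {df[c].iloc[i]!r} at row {i}, column {c!r} "
                f"(NA token is {na_token!r})"
            )
        df[c] = coerced

    exclusions = {"missing_response": 0, "all_covariates_missing": 0}
    if drop_missing_response:
        mask = df[response].isna()
        exclusions["missing_response"] = int(mask.sum())
        df = df[~mask]
    if drop_all_missing:
        mask = df[cols].isna().all(axis=1)
        exclusions["all_covariates_missing"] = int(mask.sum())
        df = df[~mask]
    if exclusions["missing_response"] or exclusions["all_covariates_missing"]:
        logger.info("exclusions applied: %s", exclusions)
    table = DataTable(
        y=df[response].to_numpy(float), X=df[cols].to_numpy(float), columns=cols
    )
    return table, exclusions


def write_table_csv(data: DataTable, path, response: str = "y", na_token: str = "NA") -> None:
    df = pd.DataFrame(data.X, columns=list(data.columns))
    df.insert(0, response, data.y)
    df.to_csv(path, index=False, na_rep=na_token)


def mnary_shift(data: DataTable, trigger_column: str, shift: float) -> DataTable:
    """Add ``shift`` to the response of every record missing the trigger column.

    Because the added signal depends on a missingness indicator (and the
    shifted response then drives nothing else), this induces an
    outcome-linked not-at-random pattern in an otherwise fixed table.
    """
    if trigger_column not in data.columns:
        raise ValueError(f"trigger column {trigger_column!r} not among covariates")
    j = list(data.columns).index(trigger_column)
    y = data.y.copy()
    y[np.isnan(data.X[:, j])] += shift
    return DataTable(y=y, X=data.X.copy(), columns=list(data.columns))


def dichotomize_at_median(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Split at the sample median; ties go to the lower class (0)."""
    y = np.asarray(y, dtype=float)
    med = float(np.median(y))
    return (y > med).astype(float), med
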