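"""Cohort table schema, validation, and delimited-text I/O.

A cohort table holds one row per participant-visit. The on-disk format is
plain CSV (UTF-8, header row, empty fields for missing values) with the
column set in :data:`SCHEMA_COLUMNS`. In memory the table is a pandas
DataFrame; the generator additionally carries a latent ``subject_intercept``
column (the subject-level random effect) which is never serialized.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Serialized column order. ``sex`` is 1 for male, 0 for female;
#: ``diagnosis`` is one of NC/MCI/AD; ``hypertension``/``diabetes`` are 0/1;
#: ``wmh_severity`` is the ordinal 0/1/2 staging (low/moderate/extensive);
#: volumes are raw mm^3 (log-transformed only inside the models).
SCHEMA_COLUMNS = [
    "id",
    "group",
    "ethnicity",
    "age",
    "sex",
    "education",
    "diagnosis",
    "bmi",
    "hypertension",
    "diabetes",
    "time_from_baseline_days",
    "wmh_severity",
    "wmh_total_mm3",
    "wmh_frontal_mm3",
    "wmh_parietal_mm3",
    "wmh_temporal_mm3",
    "wmh_occipital_mm3",
]

REGION_VOLUME_COLUMNS = [
    "wmh_total_mm3",
    "wmh_frontal_mm3",
    "wmh_parietal_mm3",
    "wmh_temporal_mm3",
    "wmh_occipital_mm3",
]

DIAGNOSIS_LEVELS = ("NC", "MCI", "AD")

#: Columns that must be present for any analysis to proceed.
REQUIRED_COLUMNS = [
    "id",
    "group",
    "age",
    "sex",
    "education",
    "diagnosis",
    "time_from_baseline_days",
]


class CohortSchemaError(ValueError):
    """Raised when a cohort table violates the schema contract."""


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table, returning it unchanged on success.

    Checks required columns, diagnosis levels, binary codings and
    non-negative visit times. Raises :class:`CohortSchemaError` listing
    offending columns / row labels.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns: {missing}")
    problems: list[str] = []

    dx = table["diagnosis"].dropna()
    bad_dx = dx[~dx.isin(DIAGNOSIS_LEVELS)]
    if len(bad_dx):
        problems.append(
            f"diagnosis outside {DIAGNOSIS_LEVELS} at rows {list(bad_dx.index[:5])}"
        )
    for col in ("sex", "hypertension", "diabetes"):
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce").dropna()
            bad = vals[~vals.isin([0, 1])]
            if len(bad):
                problems.append(f"{col} not coded 0/1 at rows {list(bad.index[:5])}")
    t = pd.to_numeric(table["time_from_baseline_days"], errors="coerce")
    neg = t[t < 0]
    if len(neg):
        problems.append(
            f"negative time_from_baseline_days at rows {list(neg.index[:5])}"
        )
    if problems:
        raise CohortSchemaError("; ".join(problems))
    return table


def baseline_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Return the baseline visit (earliest time) of each participant."""
    t = pd.to_numeric(table["time_from_baseline_days"], errors="coerce")
    order = table.assign(_t=t).sort_values(["id", "_t"], kind="mergesort")
    base = order.drop_duplicates("id", keep="first").drop(columns="_t")
    return base


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV with the canonical column set.

    Columns outside the schema (e.g. the latent ``subject_intercept``) are
    dropped; missing values are written as empty fields.
    """
    cols = [c for c in SCHEMA_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Raw tables using NACC-style vascular source columns (HYPERT / HXHYPER /
    HYPERTEN, DIABET / DIABETES, NACCBMI) are routed through
    :func:`wmhcontrast.models.harmonize_vascular_columns` before validation.
    """
    table = pd.read_csv(path, dtype={"id": str, "group": str})
    raw_vascular = {"HYPERT", "HXHYPER", "HYPERTEN", "DIABET", "DIABETES", "NACCBMI"}
    if raw_vascular & set(table.columns):
        from .models import harmonize_vascular_columns

        table = harmonize_vascular_columns(table)
    validate_cohort(table)
    return table


def require_columns(table: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns: {missing}")


def log1p_volume(values: pd.Series | np.ndarray) -> np.ndarray:
    """Natural log(volume + 1): tolerates the observed 0 mm^3 minima."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("volumes must be non-negative")
    return np.log1p(arr)
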