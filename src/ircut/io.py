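"""Cohort CSV schema, validating reader, and report writers.

The cohort file is a plain UTF-8, RFC-4180 CSV with a header and one row per
subject.  Concentrations are in conventional clinical units: glucose mg/dL,
insulin µIU/mL, lipids mg/dL, leptin ng/mL, adiponectin µg/mL; anthropometrics
in cm/kg; blood pressures in mmHg; body-fat fractions in percent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

COHORT_COLUMNS = (
    "subject_id",
    "true_group",
    "age",
    "height_cm",
    "weight_kg",
    "wc_cm",
    "hc_cm",
    "sbp",
    "dbp",
    "tfm_pct",
    "af_pct",
    "gf_pct",
    "glucose_0",
    "glucose_30",
    "glucose_60",
    "glucose_120",
    "insulin_0",
    "insulin_30",
    "insulin_60",
    "insulin_120",
    "tg",
    "tc",
    "hdl",
    "leptin",
    "adiponectin",
)

#: numeric columns that must be strictly positive
_POSITIVE = tuple(
    c for c in COHORT_COLUMNS if c not in ("subject_id", "true_group", "tfm_pct", "af_pct", "gf_pct")
)
_PERCENT = ("tfm_pct", "af_pct", "gf_pct")


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, dtypes and value domains; returns the typed table."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    table = table.copy()
    for col in COHORT_COLUMNS:
        if col in ("subject_id", "true_group"):
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna() | bad)[0])
            raise SchemaError(f"non-numeric or missing value in column {col!r}, row {row}")
        table[col] = coerced.astype(float)
    for col in _POSITIVE:
        if (table[col] <= 0).any():
            row = int(np.flatnonzero(table[col].to_numpy() <= 0)[0])
            raise SchemaError(f"nonpositive value in column {col!r}, row {row}")
    for col in _PERCENT:
        vals = table[col].to_numpy()
        if ((vals < 0) | (vals > 100)).any():
            row = int(np.flatnonzero((vals < 0) | (vals > 100))[0])
            raise SchemaError(f"{col!r} outside [0, 100] at row {row}")
    return table


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    table = pd.read_csv(path)
    return validate_cohort(table)


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[list(COHORT_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


def write_report_csv(report: pd.DataFrame, path: str | Path) -> None:
    """Write a cutoff report: 2-decimal display columns plus exact companions."""
    out = report.copy()
    for col in ("cutoff", "sensitivity", "specificity", "youden"):
        out[f"{col}_exact"] = out[col]
        out[col] = out[col].round(2)
    out.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
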