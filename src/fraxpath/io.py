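"""Cohort CSV dialect: reading, validation and lossless writing.

One row per woman.  Canonical columns: ``id, age, sex, bmi`` followed by the
seven dichotomous clinical risk factors as strict 0/1, then ``fn_tscore,
followup_years, hip_fracture_observed``.  An empty field means missing;
extra columns are preserved and column order is not significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .risk_engine import CLINICAL_RISK_FACTORS
from .synthetic import COHORT_COLUMNS

FLAG_COLUMNS = (*CLINICAL_RISK_FACTORS, "hip_fracture_observed")
FLOAT_FORMAT = "%.10g"


class CohortFormatError(ValueError):
    """The file does not conform to the cohort CSV dialect."""


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Flags must be 0, 1 or empty; malformed values raise an error naming the
    offending rows (2-based file line numbers, counting the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")
    for col in FLAG_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_missing = df[col].isna()
        bad = (~raw_missing) & (~vals.isin([0, 1]))
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise CohortFormatError(
                f"{path}: column {col!r} has non-0/1 value(s) at line(s) "
                f"{lines[:10]}")
        df[col] = vals.astype(float)
    for col in ("age", "bmi", "fn_tscore", "followup_years"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if col in ("age", "bmi") and df[col].isna().any():
            lines = (df.index[df[col].isna()] + 2).tolist()
            raise CohortFormatError(
                f"{path}: column {col!r} missing/non-numeric at line(s) "
                f"{lines[:10]}")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort losslessly: flags as bare integers, missing as empty."""
    out = cohort.copy()
    for col in FLAG_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
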