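"""Cohort table I/O and validation.

One row per subject: identifier, inclusion flag, age, sex, six binary
vascular risk factors, and (optionally) brain and per-eye retinal metric
columns. Risk factors are coded as binary presence (1) / absence (0);
missing values are preserved as missing, never imputed.
"""

from __future__ import annotations

from pathlib import Path


import pandas as pd

__all__ = [
    "RISK_FACTORS",
    "BRAIN_VARIABLES",
    "RETINAL_VARIABLES",
    "REQUIRED_COLUMNS",
    "read_cohort_table",
    "validate_cohort",
]

RISK_FACTORS = ["hypertension", "diabetes", "hypercholesterolemia", "cvd", "smoking", "stroke"]

BRAIN_VARIABLES = ["pvs_total_volume", "pvs_count", "pvs_mean_length", "pvs_mean_width", "pvs_mean_size"]

RETINAL_VARIABLES = [
    f"{side}_{m}" for side in ("left", "right") for m in ("crae", "crve", "avr", "fda", "fdv")
]

REQUIRED_COLUMNS = ["subject_id", "age", "sex"] + RISK_FACTORS

_BINARY_COLUMNS = ["sex"] + RISK_FACTORS


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a cohort DataFrame in place.

    Binary columns (sex and the six risk factors) are coerced to {0, 1}
    with missing values preserved; any other value is an error naming the
    offending column.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    df = df.copy()
    for col in _BINARY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            offending = sorted(df.loc[bad, col].astype(str).unique())
            raise ValueError(
                f"binary column {col!r} contains non-binary values {offending}; expected 0/1"
            )
        ok = vals.isna() | vals.isin([0, 1])
        if not ok.all():
            offending = sorted(vals[~ok].unique().tolist())
            raise ValueError(
                f"binary column {col!r} contains values outside {{0, 1}}: {offending}"
            )
        df[col] = vals.astype("Int64")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    for col in BRAIN_VARIABLES + RETINAL_VARIABLES + ["wmh_pct_icv"]:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "included" in df.columns:
        df["included"] = pd.to_numeric(df["included"], errors="coerce").astype("Int64")
    return df


def read_cohort_table(path) -> pd.DataFrame:
    """Read a cohort CSV (comma-separated, header row, UTF-8) and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    df = pd.read_csv(path)
    return validate_cohort(df)
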