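"""Discharge-record tables: schema, delimited-text I/O, and small helpers.

A record table is a plain :class:`pandas.DataFrame` with one row per
hospitalization (admission).  Columns:

``record_id``
    Unique string per admission.
``case_id``
    Patient/case identifier (not unique; a patient may be admitted twice).
``hospital_id``
    Hospital code.
``ownership``
    ``"public"`` or ``"private"``.
``admission_date`` / ``discharge_date``
    Calendar dates (datetime64); ``discharge_date >= admission_date``.
``length_of_stay``
    Whole days, ``discharge_date - admission_date``.
``total_charge``
    Total billed amount in LBP (>= 0).
``icd_code``
    ICD-10 discharge diagnosis, or empty string when absent.
``cpt_codes``
    Pipe-separated list of CPT procedure codes (first = primary), or empty
    string when absent.  At least one of ``icd_code`` / ``cpt_codes`` must
    be present on every row.

On disk the table is a comma-separated text file with a header row and
ISO-8601 dates, exactly as the in-memory columns above.
"""

from __future__ import annotations

import re

import pandas as pd

COLUMNS = [
    "record_id",
    "case_id",
    "hospital_id",
    "ownership",
    "admission_date",
    "discharge_date",
    "length_of_stay",
    "total_charge",
    "icd_code",
    "cpt_codes",
]

OWNERSHIPS = ("public", "private")
CASE_TYPES = ("medical", "surgical", "mixed")
STAY_CLASSES = ("short", "medium", "long")

#: ICD-10: letter, two digits, optional dot + 1-2 digits.  The dot matters:
#: three-digit (J18) and four-digit (J18.0) codes are distinct entities.
ICD_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")
#: CPT codes in this system are free-form alphanumeric identifiers.
CPT_PATTERN = re.compile(r"^[A-Za-z0-9]+$")

CPT_SEP = "|"


class SchemaError(ValueError):
    """A record table is missing columns or violates the row contract."""


def check_columns(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming any missing required column."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"record table missing required column(s): {', '.join(missing)}")


def read_records(path) -> pd.DataFrame:
    """Read a discharge-record table from delimited text.

    Dates are parsed to datetime64; absent codes come back as empty strings.
    """
    df = pd.read_csv(
        path,
        dtype={
            "record_id": str,
            "case_id": str,
            "hospital_id": str,
            "ownership": str,
            "icd_code": str,
            "cpt_codes": str,
        },
        keep_default_na=False,
        na_values=[],
    )
    check_columns(df)
    for col in ("admission_date", "discharge_date"):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    df["length_of_stay"] = df["length_of_stay"].astype(int)
    df["total_charge"] = df["total_charge"].astype(float)
    return df[COLUMNS]


def write_records(df: pd.DataFrame, path) -> None:
    """Write a record table as comma-separated text with ISO-8601 dates."""
    check_columns(df)
    out = df[COLUMNS].copy()
    for col in ("admission_date", "discharge_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def discharge_month(df: pd.DataFrame) -> pd.PeriodIndex:
    """Calendar month of discharge — the month a record belongs to downstream."""
    return pd.DatetimeIndex(df["discharge_date"]).to_period("M")


def discharge_year(df: pd.DataFrame) -> pd.Index:
    return pd.DatetimeIndex(df["discharge_date"]).year


def split_cpt(cpt_codes: pd.Series) -> pd.Series:
    """Split the pipe-separated CPT column into lists (empty list if absent)."""
    stripped = cpt_codes.fillna("").astype(str)
    return stripped.apply(lambda s: s.split(CPT_SEP) if s else [])
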