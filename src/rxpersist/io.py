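"""Reading and validating the four input claim tables.

All tables are plain CSV with ISO-8601 dates.  Column dictionary:

``pharmacy_claims.csv``
    patient_id, fill_date, product_name, quantity_ml (mL, >= 0),
    copay (>= 0); optional: form (pen | vial_syringe | other),
    route (injectable | inhaled | pump; default injectable).
``medical_claims.csv``
    patient_id, service_date, dx_codes (semicolon-separated ICD-9-CM);
    optional: drg.
``enrollment.csv``
    patient_id, start_date, end_date (closed spans, non-overlapping per
    patient).
``demographics.csv``
    patient_id plus covariate columns (gender, age, age_group, region,
    rural, capitated, charlson, er_any, inpatient_any,
    diabetes_complications, macrovascular_complications, mental_health,
    n_oad_classes).

Schema violations raise :class:`SchemaError` naming the file, column and
first offending row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dates import parse_date

__all__ = ["SchemaError", "REQUIRED_COLUMNS", "load_table", "load_tables"]

REQUIRED_COLUMNS = {
    "pharmacy_claims": ("patient_id", "fill_date", "product_name",
                        "quantity_ml", "copay"),
    "medical_claims": ("patient_id", "service_date", "dx_codes"),
    "enrollment": ("patient_id", "start_date", "end_date"),
    "demographics": ("patient_id",),
}

DATE_COLUMNS = {
    "pharmacy_claims": ("fill_date",),
    "medical_claims": ("service_date",),
    "enrollment": ("start_date", "end_date"),
    "demographics": (),
}

NONNEGATIVE_COLUMNS = {"pharmacy_claims": ("quantity_ml", "copay")}


class SchemaError(ValueError):
    """An input table violates the documented column dictionary."""


def load_table(path: str | Path, table: str) -> pd.DataFrame:
    if table not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table {table!r}")
    # dx/drg columns must stay text: an all-numeric ICD-9 column would
    # otherwise parse as float and lose trailing digits ("250.10" -> 250.1)
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "dx_codes": str, "drg": str},
        keep_default_na=True,
    )
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing columns {missing}")
    for col in DATE_COLUMNS[table]:
        parsed = []
        for i, value in enumerate(df[col]):
            try:
                parsed.append(parse_date(value))
            except (ValueError, TypeError):
                raise SchemaError(
                    f"{table}: column {col!r} row {i}: invalid date {value!r}"
                ) from None
        df[col] = parsed
    for col in NONNEGATIVE_COLUMNS.get(table, ()):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{table}: column {col!r} row {row}: "
                f"non-negative number required, got {df[col].iloc[row]!r}"
            )
        df[col] = vals
    if table == "pharmacy_claims":
        if "form" not in df.columns:
            df["form"] = "vial_syringe"
        if "route" not in df.columns:
            df["route"] = "injectable"
    if table == "medical_claims":
        df["dx_codes"] = df["dx_codes"].fillna("")
        if "drg" not in df.columns:
            df["drg"] = ""
    if table == "enrollment":
        bad = df["start_date"] > df["end_date"]
        if bad.any():
            raise SchemaError(
                f"enrollment: row {int(bad.idxmax())}: start_date > end_date"
            )
    return df


def load_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Load the four tables from a directory using the canonical file names."""
    indir = Path(indir)
    return {
        table: load_table(indir / f"{table}.csv", table)
        for table in REQUIRED_COLUMNS
    }
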