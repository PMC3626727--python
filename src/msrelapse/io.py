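"""Readers and writers for the flat claims tables.

Three CSV schemas feed the pipeline:

* ``medical_claims.csv`` — patient_id, service_start, service_end, setting,
  dx1..dx4 (ICD-9-CM, position 1 = primary), proc_codes (``;``-separated
  HCPCS/J-codes), paid_amount (USD, plan- plus patient-paid).
* ``pharmacy_claims.csv`` — patient_id, fill_date, drug_code, days_supply,
  paid_amount.
* ``enrollment.csv`` — patient_id, span_start, span_end, birth_year, sex,
  region, employment, plan_type.

Dates are ISO-8601. Paid amounts are parsed through :class:`decimal.Decimal`
into integer cents (column ``paid_cents``) so that cost sums are exact and
order-independent; they are re-serialized with two decimals. Reading a file a
writer produced is the identity on typed content.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EMPLOYMENTS, PLAN_TYPES, REGIONS, SETTINGS, SEXES, StudyConfig

logger = logging.getLogger(__name__)

DX_COLS = ["dx1", "dx2", "dx3", "dx4"]

MEDICAL_COLUMNS = ["patient_id", "service_start", "service_end", "setting",
                   *DX_COLS, "proc_codes", "paid_amount"]
PHARMACY_COLUMNS = ["patient_id", "fill_date", "drug_code", "days_supply", "paid_amount"]
ENROLLMENT_COLUMNS = ["patient_id", "span_start", "span_end", "birth_year",
                      "sex", "region", "employment", "plan_type"]


class SchemaError(ValueError):
    """A required column is missing or the header does not match the schema."""


class RowError(ValueError):
    """A row holds an unparseable or out-of-contract value; names the line."""


@dataclass
class ClaimsBundle:
    """The three typed input tables."""

    medical: pd.DataFrame
    pharmacy: pd.DataFrame
    enrollment: pd.DataFrame


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _warn_duplicates(df: pd.DataFrame, path) -> None:
    ndup = int(df.duplicated().sum())
    if ndup:
        warnings.warn(f"{path}: {ndup} exact duplicate row(s) kept", stacklevel=3)


def _parse_dates(raw: pd.Series, path, col: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.len() > 0)
    bad |= raw.isna() | (raw.astype(str).str.len() == 0)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RowError(f"{path}: line {line}: invalid date {raw[bad.idxmax()]!r} in column {col!r}")
    return parsed


def _parse_cents(raw: pd.Series, path, col: str = "paid_amount") -> pd.Series:
    def one(i, v):
        try:
            cents = Decimal(str(v)).scaleb(2).to_integral_exact()
        except (InvalidOperation, ValueError):
            raise RowError(f"{path}: line {int(i) + 2}: unparseable amount {v!r} in column {col!r}") from None
        if cents < 0:
            raise RowError(f"{path}: line {int(i) + 2}: negative amount {v!r} in column {col!r}")
        return int(cents)

    return pd.Series([one(i, v) for i, v in raw.items()], index=raw.index, dtype="int64")


def _check_enum(raw: pd.Series, allowed: tuple[str, ...], path, col: str) -> pd.Series:
    vals = raw.fillna("").astype(str)
    bad = ~vals.isin(allowed)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise RowError(f"{path}: line {line}: value {vals[bad.idxmax()]!r} not in {allowed} for column {col!r}")
    return vals


def read_medical(path, config: StudyConfig | None = None) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, MEDICAL_COLUMNS, path)
    _warn_duplicates(raw, path)
    df = pd.DataFrame({
        "patient_id": raw["patient_id"].astype(str),
        "service_start": _parse_dates(raw["service_start"], path, "service_start"),
        "service_end": _parse_dates(raw["service_end"], path, "service_end"),
        "setting": _check_enum(raw["setting"], SETTINGS, path, "setting"),
    })
    for c in DX_COLS:
        df[c] = raw[c].fillna("").astype(str)
    df["proc_codes"] = raw["proc_codes"].fillna("").astype(str)
    df["paid_cents"] = _parse_cents(raw["paid_amount"], path)
    bad = df["service_start"] > df["service_end"]
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise RowError(f"{path}: line {line}: service_start after service_end")
    return df


def read_pharmacy(path, config: StudyConfig | None = None) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, PHARMACY_COLUMNS, path)
    _warn_duplicates(raw, path)
    supply = pd.to_numeric(raw["days_supply"], errors="coerce")
    bad = supply.isna() | (supply < 1) | (supply != supply.round())
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise RowError(f"{path}: line {line}: days_supply must be a positive integer")
    return pd.DataFrame({
        "patient_id": raw["patient_id"].astype(str),
        "fill_date": _parse_dates(raw["fill_date"], path, "fill_date"),
        "drug_code": raw["drug_code"].fillna("").astype(str),
        "days_supply": supply.astype("int64"),
        "paid_cents": _parse_cents(raw["paid_amount"], path),
    })


def read_enrollment(path, config: StudyConfig | None = None) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, ENROLLMENT_COLUMNS, path)
    _warn_duplicates(raw, path)
    birth = pd.to_numeric(raw["birth_year"], errors="coerce")
    if birth.isna().any():
        line = int(birth.isna().idxmax()) + 2
        raise RowError(f"{path}: line {line}: unparseable birth_year")
    df = pd.DataFrame({
        "patient_id": raw["patient_id"].astype(str),
        "span_start": _parse_dates(raw["span_start"], path, "span_start"),
        "span_end": _parse_dates(raw["span_end"], path, "span_end"),
        "birth_year": birth.astype("int64"),
        "sex": _check_enum(raw["sex"], SEXES, path, "sex"),
        "region": _check_enum(raw["region"], REGIONS, path, "region"),
        "employment": _check_enum(raw["employment"], EMPLOYMENTS, path, "employment"),
        "plan_type": _check_enum(raw["plan_type"], PLAN_TYPES, path, "plan_type"),
    })
    bad = df["span_start"] > df["span_end"]
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise RowError(f"{path}: line {line}: span_start after span_end")
    return df


def read_claims(input_dir, config: StudyConfig | None = None) -> ClaimsBundle:
    """Load the three tables from a directory and log a load report."""
    d = Path(input_dir)
    bundle = ClaimsBundle(
        medical=read_medical(d / "medical_claims.csv", config),
        pharmacy=read_pharmacy(d / "pharmacy_claims.csv", config),
        enrollment=read_enrollment(d / "enrollment.csv", config),
    )
    for name, df, datecol in (("medical", bundle.medical, "service_start"),
                              ("pharmacy", bundle.pharmacy, "fill_date"),
                              ("enrollment", bundle.enrollment, "span_start")):
        logger.info("loaded %s: %d rows, %d patients, dates %s..%s",
                    name, len(df), df["patient_id"].nunique(),
                    df[datecol].min(), df[datecol].max())
    return bundle


# ---------------------------------------------------------------------------
# writing

_CANONICAL_ORDER = {
    frozenset(MEDICAL_COLUMNS): MEDICAL_COLUMNS,
    frozenset(PHARMACY_COLUMNS): PHARMACY_COLUMNS,
    frozenset(ENROLLMENT_COLUMNS): ENROLLMENT_COLUMNS,
}


def write_table(df: pd.DataFrame, path) -> None:
    """Write any analysis table as CSV with stable column order.

    Datetime columns are serialized as ISO dates; an integer ``paid_cents``
    column is serialized back to a two-decimal ``paid_amount``. Writing the
    same table twice yields byte-identical files.
    """
    if df is None:
        raise ValueError("records must not be None")
    out = df.copy()
    if "paid_cents" in out.columns:
        out["paid_amount"] = out["paid_cents"].map(lambda c: f"{c // 100}.{c % 100:02d}")
        out = out.drop(columns=["paid_cents"])
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    order = _CANONICAL_ORDER.get(frozenset(out.columns))
    if order:
        out = out[order]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, lineterminator="\n")


def write_claims(bundle: ClaimsBundle, output_dir) -> None:
    d = Path(output_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_table(bundle.medical, d / "medical_claims.csv")
    write_table(bundle.pharmacy, d / "pharmacy_claims.csv")
    write_table(bundle.enrollment, d / "enrollment.csv")
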