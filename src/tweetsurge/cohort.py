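"""Death-record parsing, cause selection, recoding and the lagged merge.

Records flow through: parse -> cause selection (ICD-10 ranges) ->
exclusions -> age-group recoding -> date-keyed merge with the exposure
calendar at a fixed lag.  Every data-reducing step reports before/after
counts so a run is auditable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exposure import ExposureCalendar

logger = logging.getLogger(__name__)

__all__ = [
    "DeathRecord",
    "ParseReport",
    "SUICIDE_RANGES",
    "UNEXPECTED_RANGES",
    "parse_records",
    "icd10_in_range",
    "select_cause",
    "apply_exclusions",
    "derive_age_group",
    "merge_with_lag",
]

#: intentional self-harm
SUICIDE_RANGES = [("X60", "X84")]
#: other external causes / unexpected deaths used for the sensitivity analysis
#: (note the stated ranges leave out X85-Y00, assault)
UNEXPECTED_RANGES = [("W00", "X59"), ("Y01", "Y59")]

RECORD_COLUMNS = ["date", "age", "sex", "occupation", "marital_status", "area", "icd10"]

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")
_RANGE_RE = re.compile(r"^[A-Z][0-9]{2}$")

SEXES = {"male", "female"}
OCCUPATIONS = {"agriculture", "self-employed", "corporate", "other", "unemployed"}
MARITAL = {"married", "unmarried", "widowed", "divorced", "other"}
AREAS = {"urban", "rural"}


@dataclass
class DeathRecord:
    """One individual death record."""

    death_date: pd.Timestamp
    age: Optional[int]
    sex: str
    occupation: Optional[str]
    marital_status: str
    area: str
    icd10: str

    def __post_init__(self) -> None:
        if not _ICD_RE.match(self.icd10):
            raise ValueError(f"malformed ICD-10 code {self.icd10!r}")
        if self.age is not None and not 0 <= self.age <= 130:
            raise ValueError(f"age {self.age} outside [0, 130]")


@dataclass
class ParseReport:
    """Outcome of parsing a records file: row counts and per-row errors."""

    n_rows: int = 0
    n_parsed: int = 0
    errors: list = field(default_factory=list)  # (row_number, message)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def parse_records(path_or_buffer) -> tuple[pd.DataFrame, ParseReport]:
    """Read a death-records CSV into a typed frame.

    Expects columns date, age, sex, occupation, marital_status, area,
    icd10 (extra columns are preserved).  A missing required column is
    fatal; an unparseable field rejects only that row, which is listed in
    the report with its 1-based data row number.
    """
    df = pd.read_csv(path_or_buffer, dtype=str, keep_default_na=False)
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"records CSV is missing required column {col!r}")

    report = ParseReport(n_rows=len(df))
    bad = pd.Series(False, index=df.index)

    def reject(mask: pd.Series, message: str) -> None:
        for idx in df.index[mask & ~bad]:
            report.errors.append((int(idx) + 1, f"{message}: {dict(df.loc[idx])}"))
        bad[mask] = True

    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    reject(dates.isna(), "unparseable date")

    age_str = df["age"].str.strip()
    age = pd.to_numeric(age_str, errors="coerce")
    reject((age_str != "") & age.isna(), "non-integer age")
    reject((age < 0) | (age > 130), "age outside [0, 130]")

    reject(~df["icd10"].str.match(_ICD_RE), "malformed ICD-10 code")
    reject((df["sex"] != "") & ~df["sex"].isin(SEXES), "unknown sex")
    reject(
        (df["occupation"] != "") & ~df["occupation"].isin(OCCUPATIONS),
        "unknown occupation",
    )
    reject(~df["marital_status"].isin(MARITAL), "unknown marital status")
    reject(~df["area"].isin(AREAS), "unknown area")

    keep = ~bad
    out = pd.DataFrame(
        {
            "date": dates[keep].dt.normalize(),
            "age": age[keep],
            "sex": df.loc[keep, "sex"].replace("", None),
            "occupation": df.loc[keep, "occupation"].replace("", None),
            "marital_status": df.loc[keep, "marital_status"],
            "area": df.loc[keep, "area"],
            "icd10": df.loc[keep, "icd10"],
        }
    ).reset_index(drop=True)
    for col in df.columns:
        if col not in RECORD_COLUMNS:
            out[col] = df.loc[keep, col].reset_index(drop=True)
    report.n_parsed = len(out)
    logger.info(
        "parsed %d/%d records (%d rejected)",
        report.n_parsed,
        report.n_rows,
        report.n_rejected,
    )
    return out, report


def _check_range(lo: str, hi: str) -> None:
    if not (_RANGE_RE.match(lo) and _RANGE_RE.match(hi)) or lo > hi:
        raise ValueError(f"malformed ICD-10 range {lo!r}-{hi!r}")


def icd10_in_range(code: str, range_spec) -> bool:
    """True if the 3-character prefix of *code* falls in any of the
    inclusive ranges, ordered by letter then two-digit number (the 4th
    character is ignored)."""
    if not _ICD_RE.match(code):
        raise ValueError(f"malformed ICD-10 code {code!r}")
    prefix = code[:3]
    for lo, hi in range_spec:
        _check_range(lo, hi)
        if lo <= prefix <= hi:  # letter+2digit strings order lexicographically
            return True
    return False


def select_cause(records: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Keep records whose cause code falls in the mode's ICD-10 ranges:
    ``suicide`` (X60-X84) or ``unexpected`` (W00-X59, Y01-Y59)."""
    ranges = {"suicide": SUICIDE_RANGES, "unexpected": UNEXPECTED_RANGES}.get(mode)
    if ranges is None:
        raise ValueError(f"mode must be 'suicide' or 'unexpected', got {mode!r}")
    if records.empty:
        return records.copy()
    prefix = records["icd10"].str[:3]
    mask = np.zeros(len(records), dtype=bool)
    for lo, hi in ranges:
        _check_range(lo, hi)
        mask |= ((prefix >= lo) & (prefix <= hi)).to_numpy()
    out = records[mask].reset_index(drop=True)
    logger.info("select_cause(%s): kept %d/%d records", mode, len(out), len(records))
    return out


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop records with missing age, missing occupation, or marital
    status 'other'.  Returns the kept frame and drop counts by reason."""
    missing_age = records["age"].isna()
    missing_occ = records["occupation"].isna()
    marital_other = records["marital_status"] == "other"
    drops = {
        "missing_age": int(missing_age.sum()),
        "missing_occupation": int((missing_occ & ~missing_age).sum()),
        "marital_other": int((marital_other & ~missing_age & ~missing_occ).sum()),
    }
    keep = ~(missing_age | missing_occ | marital_other)
    out = records[keep].reset_index(drop=True)
    logger.info("exclusions: kept %d/%d, drops=%s", len(out), len(records), drops)
    return out, drops


def derive_age_group(age) -> pd.Series:
    """Binarize age: 'young' for 40 or younger, else 'old'.

    Accepts a scalar or a Series of non-missing ages.
    """
    if np.isscalar(age):
        if pd.isna(age):
            raise ValueError("age is missing")
        return "young" if age <= 40 else "old"
    age = pd.Series(age)
    if age.isna().any():
        raise ValueError("age contains missing values; apply exclusions first")
    return pd.Series(np.where(age <= 40, "young", "old"), index=age.index)


def merge_with_lag(
    records: pd.DataFrame, calendar: ExposureCalendar, lag_days: int
) -> tuple[pd.DataFrame, int]:
    """Date-keyed merge: each record gets the exposure of its death date
    minus ``lag_days``.

    Records whose lagged date is outside the calendar or has undefined
    exposure are dropped.  Returns (analysis rows, number dropped); the
    rows carry ``exposed`` (bool) and ``lag_days`` columns.
    """
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")
    cal = pd.Series(calendar.exposed, index=calendar.dates)
    lagged = pd.DatetimeIndex(records["date"]) - pd.Timedelta(days=lag_days)
    exposure = cal.reindex(lagged).to_numpy()
    keep = ~np.isnan(exposure)
    out = records[keep].reset_index(drop=True)
    out["exposed"] = exposure[keep].astype(bool)
    out["lag_days"] = lag_days
    n_dropped = int((~keep).sum())
    logger.info(
        "merge_with_lag(%d): kept %d, dropped %d (undefined exposure)",
        lag_days,
        len(out),
        n_dropped,
    )
    return out, n_dropped
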