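"""Domain types, CSV I/O and validation for household budget survey microdata.

The unit of analysis is the household. Each record carries a survey
expansion weight, the three expenditure aggregates the indicators need
(total consumption, food, out-of-pocket health), and the head-of-household
demographics used for stratification and the determinants model.

All money fields of a dataset share one currency and one accounting period
(monthly by default); out-of-pocket health spending is a component of total
expenditure (health is one of the twelve COICOP divisions), so OOP budget
shares are bounded by 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "REGIONS",
    "SEXES",
    "MARITAL_LEVELS",
    "EDUCATION_LEVELS",
    "ACTIVITY_LEVELS",
    "VALIDATION_RULES",
    "HouseholdRecord",
    "SurveyDataset",
    "ValidationReport",
    "SchemaError",
    "EmptyDatasetError",
    "read_survey",
    "write_survey",
    "validate_survey",
    "write_table",
]

CANONICAL_COLUMNS = [
    "household_id",
    "weight",
    "survey_year",
    "region",
    "household_size",
    "total_expenditure",
    "food_expenditure",
    "oop_health",
    "head_sex",
    "head_marital",
    "head_education",
    "head_activity",
    "has_child_under5",
    "has_elderly_over60",
]

REGIONS = ("urban", "rural")
SEXES = ("male", "female")
MARITAL_LEVELS = ("married", "widowed", "divorced", "separated", "single")
EDUCATION_LEVELS = ("primary", "secondary_plus")
ACTIVITY_LEVELS = ("employed", "homemaker", "student", "retired", "unemployed", "other")

_ENUM_DOMAINS = {
    "region": REGIONS,
    "head_sex": SEXES,
    "head_marital": MARITAL_LEVELS,
    "head_education": EDUCATION_LEVELS,
    "head_activity": ACTIVITY_LEVELS,
}

_MONEY_COLUMNS = ("total_expenditure", "food_expenditure", "oop_health")

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


class SchemaError(ValueError):
    """Input header or schema mapping does not provide a required column."""


class EmptyDatasetError(ValueError):
    """No valid household rows remain after parsing and validation."""


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household — the unit of every indicator."""

    household_id: str
    weight: float
    survey_year: str
    region: str
    household_size: int
    total_expenditure: float
    food_expenditure: float
    oop_health: float
    head_sex: str
    head_marital: str
    head_education: str
    head_activity: str
    has_child_under5: bool
    has_elderly_over60: bool

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in CANONICAL_COLUMNS}


@dataclass
class SurveyDataset:
    """A weighted collection of households with currency/period metadata.

    ``frame`` holds one row per household in canonical column order; all
    money columns are in ``currency`` units per ``period``.
    """

    frame: pd.DataFrame
    currency: str = "MUR"
    period: str = "monthly"

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame lacks canonical columns: {missing}")
        if len(self.frame) == 0:
            raise EmptyDatasetError("a SurveyDataset must contain at least one household")
        self.frame = self.frame[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[HouseholdRecord]:
        return [HouseholdRecord(**row) for row in self.frame.to_dict("records")]

    @classmethod
    def from_records(
        cls, records: Iterable[HouseholdRecord], currency: str = "MUR", period: str = "monthly"
    ) -> "SurveyDataset":
        frame = pd.DataFrame([r.as_dict() for r in records], columns=CANONICAL_COLUMNS)
        return cls(frame, currency=currency, period=period)

    def equals(self, other: "SurveyDataset") -> bool:
        if self.currency != other.currency or self.period != other.period:
            return False
        try:
            pd.testing.assert_frame_equal(
                self.frame, other.frame, check_dtype=False, check_exact=False
            )
        except AssertionError:
            return False
        return True


@dataclass
class ValidationReport:
    """Outcome of row validation: counts plus (row index, violated rule)."""

    accepted_count: int
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def rejected_count(self) -> int:
        return len(self.rejections)


def _rule_weight_nonpositive(r: Mapping) -> bool:
    return not (r["weight"] > 0)


def _rule_household_size(r: Mapping) -> bool:
    return not (r["household_size"] >= 1)


def _rule_negative_money(col: str):
    def rule(r: Mapping) -> bool:
        return not (r[col] >= 0)

    return rule


def _rule_food_exceeds_total(r: Mapping) -> bool:
    return r["food_expenditure"] > r["total_expenditure"]


def _rule_oop_exceeds_total(r: Mapping) -> bool:
    return r["oop_health"] > r["total_expenditure"]


def _rule_bad_enum(col: str):
    domain = _ENUM_DOMAINS[col]

    def rule(r: Mapping) -> bool:
        return r[col] not in domain

    return rule


#: Documented rule order: a rejected row carries the FIRST rule it violates.
VALIDATION_RULES: list[tuple[str, object]] = [
    ("weight_nonpositive", _rule_weight_nonpositive),
    ("household_size_lt_1", _rule_household_size),
    ("negative_total_expenditure", _rule_negative_money("total_expenditure")),
    ("negative_food_expenditure", _rule_negative_money("food_expenditure")),
    ("negative_oop_health", _rule_negative_money("oop_health")),
    ("food_exceeds_total", _rule_food_exceeds_total),
    ("oop_exceeds_total", _rule_oop_exceeds_total),
    ("invalid_region", _rule_bad_enum("region")),
    ("invalid_head_sex", _rule_bad_enum("head_sex")),
    ("invalid_head_marital", _rule_bad_enum("head_marital")),
    ("invalid_head_education", _rule_bad_enum("head_education")),
    ("invalid_head_activity", _rule_bad_enum("head_activity")),
    # Uniqueness is checked last, over rows that passed the per-row rules;
    # the *later* duplicate of a (survey_year, household_id) pair is rejected.
    ("duplicate_household_id", None),
]


def validate_survey(
    rows: pd.DataFrame, currency: str = "MUR", period: str = "monthly"
) -> tuple[SurveyDataset | None, ValidationReport]:
    """Validate parsed rows against the household invariants.

    Rejection is data, not failure: each rejected row is reported with the
    first rule it violates, in the documented rule order. Returns ``None``
    for the dataset when no row survives.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"rows lack canonical columns: {missing}")
    rows = rows[CANONICAL_COLUMNS].reset_index(drop=True)

    rejections: list[tuple[int, str]] = []
    keep_mask = np.ones(len(rows), dtype=bool)
    records = rows.to_dict("records")
    for i, rec in enumerate(records):
        for name, rule in VALIDATION_RULES:
            if rule is None:
                continue
            try:
                violated = rule(rec)
            except TypeError:  # unparseable value in a numeric field
                violated = True
            if violated:
                rejections.append((i, name))
                keep_mask[i] = False
                break

    seen: set[tuple[str, str]] = set()
    for i, rec in enumerate(records):
        if not keep_mask[i]:
            continue
        key = (str(rec["survey_year"]), str(rec["household_id"]))
        if key in seen:
            rejections.append((i, "duplicate_household_id"))
            keep_mask[i] = False
        else:
            seen.add(key)

    rejections.sort(key=lambda t: t[0])
    accepted = rows[keep_mask]
    report = ValidationReport(accepted_count=len(accepted), rejections=rejections)
    if len(accepted) == 0:
        return None, report
    return SurveyDataset(accepted, currency=currency, period=period), report


def _parse_enum(series: pd.Series, col: str) -> pd.Series:
    out = series.astype(str).str.strip().str.lower().str.replace(" ", "_")
    if col == "head_education":
        out = out.replace({"secondary+": "secondary_plus", "secondary_and_above": "secondary_plus"})
    return out


def _parse_bool(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    return s.map(lambda v: True if v in _TRUTHY else (False if v in _FALSY else None))


def read_survey(
    path,
    schema: Mapping[str, str] | None = None,
    currency: str = "MUR",
    period: str = "monthly",
    return_report: bool = False,
):
    """Read a delimited household file into a validated :class:`SurveyDataset`.

    Parameters
    ----------
    path
        CSV file (RFC-4180, UTF-8, header row).
    schema
        Optional mapping from canonical column name to the column name used
        in the file, for binding foreign headers.
    return_report
        Also return the :class:`ValidationReport`.
    """
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"no household rows in {path!s}") from exc
    if raw.shape[1] == 0 or len(raw) == 0:
        raise EmptyDatasetError(f"no household rows in {path!s}")

    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SchemaError(f"header of {path!s} lacks mapped column(s): {sorted(missing)}")
    df = raw.rename(columns=rename)[CANONICAL_COLUMNS].copy()

    df["household_id"] = df["household_id"].astype(str)
    df["survey_year"] = df["survey_year"].astype(str)
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce")
    df["household_size"] = pd.to_numeric(df["household_size"], errors="coerce")
    for col in _MONEY_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _ENUM_DOMAINS:
        df[col] = _parse_enum(df[col], col)
    for col in ("has_child_under5", "has_elderly_over60"):
        df[col] = _parse_bool(df[col])
    # NaN from unparseable numerics fails the corresponding >= rule.
    df["household_size"] = df["household_size"].astype("float")

    ds, report = validate_survey(df, currency=currency, period=period)
    if ds is None:
        raise EmptyDatasetError(f"zero valid rows in {path!s} ({report.rejections[:5]} ...)")
    ds.frame["household_size"] = ds.frame["household_size"].astype(int)
    if return_report:
        return ds, report
    return ds


def write_survey(ds: SurveyDataset, path) -> None:
    """Write a dataset back to canonical CSV (round-trips through read_survey)."""
    ds.frame.to_csv(path, index=False)


def write_table(table: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a result table as CSV with header; numeric cells at documented precision."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    table.to_csv(path, index=False, float_format=float_format)
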