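"""Ingest participant-level survey CSVs, derive missing variables, apply exclusions.

The exclusion cascade mirrors the study-sample flow chart of the surveillance
analyses this package supports: drop people who did not inject recently, then
image-and-performance-only injectors, then records with insufficient data to
derive age / age at first injection / year of first injection / duration, then
implausible records.  Each record is counted once, at the first rule it
violates, so the counts always reconcile with the input total.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SURVEY_COLUMNS

#: fields that must all be present (or derivable) after cleaning
CORE_FIELDS = ["age", "age_first_inj", "year_first_inj", "duration"]

#: tolerance (years) between reported duration and survey_year - year_first_inj
#: before a complete record is declared implausible; ages and years are reported
#: at whole-year granularity so the two can legitimately differ by one
CONSISTENCY_TOL = 1

RECENCY_MODES = ("strict", "assume_recent_pre1993", "last_inj_year")

_INT_COLS = [
    "survey_year",
    "age",
    "age_first_inj",
    "year_first_inj",
    "duration",
    "recent_inj",
    "psychoactive",
]


@dataclass
class ExclusionLog:
    """Ordered accounting of the exclusion cascade (one count per rule)."""

    input: int = 0
    excluded_not_recent: int = 0
    excluded_performance_only: int = 0
    excluded_insufficient: int = 0
    excluded_implausible: int = 0
    retained: int = 0

    def total_excluded(self) -> int:
        return (
            self.excluded_not_recent
            + self.excluded_performance_only
            + self.excluded_insufficient
            + self.excluded_implausible
        )

    def reconciles(self) -> bool:
        return self.input - self.total_excluded() == self.retained

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def read_survey_csv(path) -> pd.DataFrame:
    """Read a participant-level CSV in the canonical schema.

    The header must contain exactly the canonical columns (an optional
    ``last_inj_year`` column is allowed for the year-of-last-injection recency
    dialect).  Empty strings are missing values; numeric columns become
    nullable integers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    allowed_extra = {"last_inj_year"}
    missing = [c for c in SURVEY_COLUMNS if c not in cols]
    extra = [c for c in cols if c not in SURVEY_COLUMNS and c not in allowed_extra]
    if missing or extra:
        raise ValueError(
            f"malformed survey CSV header: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    df = df.replace("", pd.NA)
    for col in _INT_COLS + (["last_inj_year"] if "last_inj_year" in cols else []):
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    return df


def derive_fields(table: pd.DataFrame) -> pd.DataFrame:
    """Fill derivable fields without overwriting observed values.

    Uses the identities ``duration = age - age_first_inj`` and
    ``year_first_inj = survey_year - duration`` (and their rearrangements);
    iterates to a fixed point so chained derivations resolve.  Records that
    remain incomplete are left for :func:`apply_exclusions`.
    """
    df = table.copy()
    for _ in range(2):
        df["duration"] = df["duration"].fillna(df["age"] - df["age_first_inj"])
        df["duration"] = df["duration"].fillna(df["survey_year"] - df["year_first_inj"])
        df["age"] = df["age"].fillna(df["age_first_inj"] + df["duration"])
        df["age_first_inj"] = df["age_first_inj"].fillna(df["age"] - df["duration"])
        df["year_first_inj"] = df["year_first_inj"].fillna(
            df["survey_year"] - df["duration"]
        )
    return df


def _recency_fail_mask(df: pd.DataFrame, recency_mode: str) -> np.ndarray:
    recent = df["recent_inj"]
    no = (recent == 0).fillna(False).to_numpy()
    unknown = recent.isna().to_numpy()
    if recency_mode == "strict":
        return no | unknown
    if recency_mode == "assume_recent_pre1993":
        pre93 = (df["survey_year"] <= 1992).fillna(False).to_numpy()
        return no | (unknown & ~pre93)
    if recency_mode == "last_inj_year":
        if "last_inj_year" not in df.columns:
            raise ValueError(
                "recency_mode 'last_inj_year' requires a last_inj_year column"
            )
        recent_by_year = (
            (df["last_inj_year"] >= df["survey_year"] - 1).fillna(False).to_numpy()
        )
        yes = (recent == 1).fillna(False).to_numpy()
        return ~(yes | recent_by_year)
    raise ValueError(f"unknown recency_mode {recency_mode!r}; use one of {RECENCY_MODES}")


def apply_exclusions(
    table: pd.DataFrame, recency_mode: str = "strict"
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion cascade to a derived table.

    Rules, in order, each record counted at the first it violates:

    1. not injecting recently (``recent_inj`` = no, or unknown per
       ``recency_mode``);
    2. image-and-performance-only injectors (``psychoactive`` = no; unknown is
       retained — not all surveys ask);
    3. still missing any of age / age at first injection / year of first
       injection / duration after derivation;
    4. implausible: age at first injection greater than current age, year of
       first injection after the survey year, negative duration, duration not
       equal to ``age - age_first_inj``, or duration and
       ``survey_year - year_first_inj`` disagreeing by more than
       ±``CONSISTENCY_TOL`` years (the year arithmetic gets a one-year grace
       because ages and years are reported at whole-year granularity).

    Returns the clean table and an :class:`ExclusionLog` whose counts
    reconcile with the input size.  Idempotent on its own output.
    """
    log = ExclusionLog(input=len(table))
    if len(table) == 0:
        return table.copy(), log
    df = table

    fail_recent = _recency_fail_mask(df, recency_mode)
    alive = ~fail_recent
    log.excluded_not_recent = int(fail_recent.sum())

    fail_perf = (df["psychoactive"] == 0).fillna(False).to_numpy() & alive
    log.excluded_performance_only = int(fail_perf.sum())
    alive &= ~fail_perf

    missing_any = df[CORE_FIELDS].isna().any(axis=1).to_numpy()
    fail_missing = missing_any & alive
    log.excluded_insufficient = int(fail_missing.sum())
    alive &= ~fail_missing

    implausible = (
        (df["age_first_inj"] > df["age"])
        | (df["year_first_inj"] > df["survey_year"])
        | (df["duration"] < 0)
        | (df["duration"] != df["age"] - df["age_first_inj"])
        | (
            (df["duration"] - (df["survey_year"] - df["year_first_inj"])).abs()
            > CONSISTENCY_TOL
        )
    ).fillna(False).to_numpy()
    fail_impl = implausible & alive
    log.excluded_implausible = int(fail_impl.sum())
    alive &= ~fail_impl

    clean = df[alive].copy()
    log.retained = int(alive.sum())
    assert log.reconciles()
    return clean, log


def clean_survey_table(
    table: pd.DataFrame, recency_mode: str = "strict"
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Derive fields then apply the exclusion cascade (the standard entry point)."""
    return apply_exclusions(derive_fields(table), recency_mode=recency_mode)
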