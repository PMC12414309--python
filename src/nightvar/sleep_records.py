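"""Data model and I/O for nightly actigraphy-derived sleep series.

The unit of observation is one person-night carrying up to three metrics:
sleep duration (minutes), bedtime and waketime (minutes relative to
midnight, negative = before midnight).  Persons additionally carry
demographics and two-rater psychopathology facet scores.  Missing values
are ``NaN`` in memory and empty cells on disk — never coded as 0 or -999.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Psychopathology facets: anxious/depressed, withdrawn/depressed, somatic,
#: oppositional defiance, conduct, hyperactivity, inattention, emotion
#: dysregulation.
FACETS: tuple[str, ...] = ("ad", "wd", "som", "odd", "cd", "hyp", "at", "eri")

#: Raters: caregiver and youth self-report.
RATERS: tuple[str, ...] = ("cg", "yr")

#: Sleep metric column names in nights.csv order.
SLEEP_METRICS: tuple[str, ...] = ("duration_min", "bedtime_min", "waketime_min")

PERSON_COLUMNS: tuple[str, ...] = (
    "person_id",
    "age",
    "sex",
    "maternal_education",
    "income_to_needs",
) + tuple(f"{f}_{r}" for f in FACETS for r in RATERS)

NIGHT_COLUMNS: tuple[str, ...] = (
    "person_id",
    "night_index",
    "weekend",
) + SLEEP_METRICS


@dataclass(frozen=True)
class NightlyRecord:
    """One person-night of sleep metrics; any metric may be NaN."""

    person_id: str
    night_index: int
    weekend: int
    duration_min: float = math.nan
    bedtime_min: float = math.nan
    waketime_min: float = math.nan

    def __post_init__(self) -> None:
        if self.night_index < 0:
            raise ValueError("night_index must be >= 0")
        if self.weekend not in (0, 1):
            raise ValueError("weekend must be 0 or 1")
        if not math.isnan(self.duration_min) and not (0.0 <= self.duration_min <= 1440.0):
            raise ValueError("duration_min must lie in [0, 1440] minutes")

    @property
    def observed(self) -> bool:
        """True if at least one sleep metric is non-missing."""
        return not (
            math.isnan(self.duration_min)
            and math.isnan(self.bedtime_min)
            and math.isnan(self.waketime_min)
        )


@dataclass(frozen=True)
class PersonProfile:
    """Demographics plus 8 facets x 2 raters of psychopathology scores."""

    person_id: str
    age: float = math.nan
    sex: float = math.nan
    maternal_education: float = math.nan
    income_to_needs: float = math.nan
    facet_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {
            k for k in self.facet_scores
            if k not in {f"{f}_{r}" for f in FACETS for r in RATERS}
        }
        if unknown:
            raise ValueError(f"unknown facet score keys: {sorted(unknown)}")


#: Minimum observed nights for a person's sleep data to count as valid.
DEFAULT_MIN_NIGHTS = 3


@dataclass
class NightlySeries:
    """Ordered nightly records for one person, with a validity flag.

    ``valid_sleep`` is derived unless set explicitly: at least
    ``DEFAULT_MIN_NIGHTS`` records with at least one observed metric
    (see :func:`apply_validity_filter`).
    """

    person_id: str
    records: list[NightlyRecord] = field(default_factory=list)
    valid_sleep: bool | None = None

    def __post_init__(self) -> None:
        idx = [r.night_index for r in self.records]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("night_index must be strictly increasing")
        if self.valid_sleep is None:
            self.valid_sleep = self.n_observed >= DEFAULT_MIN_NIGHTS

    @property
    def n_observed(self) -> int:
        return sum(r.observed for r in self.records)


def center_clock_time(hour: int, minute: int, after_midnight: bool) -> float:
    """Convert a clock reading to minutes relative to midnight.

    Pre-midnight readings are negative (23:30 -> -30), post-midnight
    positive (01:15 -> 75), midnight itself 0 regardless of the flag.
    """
    if not (0 <= hour <= 23 and 0 <= minute <= 59):
        raise ValueError("invalid clock time")
    m = 60 * hour + minute
    if m == 0:
        return 0.0
    return float(m) if after_midnight else float(m - 1440)


def apply_validity_filter(
    series: NightlySeries, min_nights: int = DEFAULT_MIN_NIGHTS
) -> NightlySeries:
    """Mask all sleep metrics for persons with < ``min_nights`` observed nights.

    Persons are never dropped: an invalid series keeps its rows (and the
    night/weekend structure) but every metric becomes missing, matching a
    full-information analysis that retains such cases with sleep missing.
    """
    if min_nights < 1:
        raise ValueError("min_nights must be >= 1")
    if series.n_observed >= min_nights:
        return NightlySeries(series.person_id, list(series.records), valid_sleep=True)
    masked = [
        replace(r, duration_min=math.nan, bedtime_min=math.nan, waketime_min=math.nan)
        for r in series.records
    ]
    return NightlySeries(series.person_id, masked, valid_sleep=False)


# ---------------------------------------------------------------------------
# Tabular I/O

def persons_to_frame(profiles: Iterable[PersonProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "person_id": p.person_id,
            "age": p.age,
            "sex": p.sex,
            "maternal_education": p.maternal_education,
            "income_to_needs": p.income_to_needs,
        }
        for f in FACETS:
            for r in RATERS:
                row[f"{f}_{r}"] = p.facet_scores.get(f"{f}_{r}", math.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(PERSON_COLUMNS))


def nights_to_frame(series: Iterable[NightlySeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for r in s.records:
            rows.append(
                {
                    "person_id": r.person_id,
                    "night_index": r.night_index,
                    "weekend": r.weekend,
                    "duration_min": r.duration_min,
                    "bedtime_min": r.bedtime_min,
                    "waketime_min": r.waketime_min,
                }
            )
    return pd.DataFrame(rows, columns=list(NIGHT_COLUMNS))


def _profiles_from_frame(df: pd.DataFrame) -> list[PersonProfile]:
    profiles = []
    for _, row in df.iterrows():
        scores = {
            f"{f}_{r}": float(row[f"{f}_{r}"])
            for f in FACETS
            for r in RATERS
            if f"{f}_{r}" in row
        }
        profiles.append(
            PersonProfile(
                person_id=str(row["person_id"]),
                age=float(row["age"]),
                sex=float(row["sex"]),
                maternal_education=float(row["maternal_education"]),
                income_to_needs=float(row["income_to_needs"]),
                facet_scores=scores,
            )
        )
    return profiles


def _series_from_frame(
    nights: pd.DataFrame, person_ids: Sequence[str]
) -> list[NightlySeries]:
    by_person: dict[str, list[NightlyRecord]] = {pid: [] for pid in person_ids}
    for _, row in nights.iterrows():
        pid = str(row["person_id"])
        if pid not in by_person:
            raise ValueError(f"night row references unknown person_id {pid!r}")
        by_person[pid].append(
            NightlyRecord(
                person_id=pid,
                night_index=int(row["night_index"]),
                weekend=int(row["weekend"]),
                duration_min=float(row["duration_min"]),
                bedtime_min=float(row["bedtime_min"]),
                waketime_min=float(row["waketime_min"]),
            )
        )
    out = []
    for pid in person_ids:
        recs = sorted(by_person[pid], key=lambda r: r.night_index)
        out.append(NightlySeries(pid, recs))
    return out


def read_cohort(
    person_path: str | Path, nights_path: str | Path
) -> tuple[list[PersonProfile], list[NightlySeries]]:
    """Read persons.csv + nights.csv into typed collections.

    Every person in the nights table must appear in the person table
    (error naming the offending id otherwise); persons with zero nightly
    rows are retained with an empty series.  Malformed numeric fields are
    reported with their row number.
    """
    persons_df = pd.read_csv(person_path, dtype={"person_id": str})
    missing_cols = set(PERSON_COLUMNS) - set(persons_df.columns)
    if missing_cols:
        raise ValueError(f"persons file missing columns: {sorted(missing_cols)}")
    nights_df = pd.read_csv(nights_path, dtype={"person_id": str})
    missing_cols = set(NIGHT_COLUMNS) - set(nights_df.columns)
    if missing_cols:
        raise ValueError(f"nights file missing columns: {sorted(missing_cols)}")

    for col in ("night_index", "weekend") + SLEEP_METRICS:
        coerced = pd.to_numeric(nights_df[col], errors="coerce")
        bad = coerced.isna() & nights_df[col].notna()
        if bad.any():
            rownum = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"malformed numeric field {col!r} at nights.csv row {rownum}")
        nights_df[col] = coerced
    for col in PERSON_COLUMNS[1:]:
        coerced = pd.to_numeric(persons_df[col], errors="coerce")
        bad = coerced.isna() & persons_df[col].notna()
        if bad.any():
            rownum = int(bad.idxmax()) + 2
            raise ValueError(f"malformed numeric field {col!r} at persons.csv row {rownum}")
        persons_df[col] = coerced

    profiles = _profiles_from_frame(persons_df)
    series = _series_from_frame(nights_df, [p.person_id for p in profiles])
    return profiles, series


def write_cohort(
    profiles: Iterable[PersonProfile],
    series: Iterable[NightlySeries],
    person_path: str | Path,
    nights_path: str | Path,
) -> None:
    """Write persons.csv / nights.csv (empty cells for missing values)."""
    persons_to_frame(profiles).to_csv(person_path, index=False)
    nights_to_frame(series).to_csv(nights_path, index=False)


def person_descriptives(series: Iterable[NightlySeries]) -> pd.DataFrame:
    """Per-person mean and sample SD (n-1) of each metric across observed nights.

    Missing nights are excluded pairwise per metric; persons with fewer
    than 2 observations of a metric get a missing SD, persons with none
    get missing mean and SD — the row is still present.
    """
    rows = []
    for s in series:
        row: dict[str, float | str] = {"person_id": s.person_id}
        df = nights_to_frame([s])
        for m in SLEEP_METRICS:
            vals = df[m].dropna() if len(df) else pd.Series(dtype=float)
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) >= 1 else math.nan
            row[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else math.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    return out


def cohort_descriptives(series: Iterable[NightlySeries]) -> pd.DataFrame:
    """Cohort-level mean/SD of the per-person means and SDs."""
    per = person_descriptives(series).drop(columns=["person_id"])
    return pd.DataFrame({"mean": per.mean(), "sd": per.std(ddof=1)})
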