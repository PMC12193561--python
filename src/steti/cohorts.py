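"""Diagnosis-year and death-year cohort tables built from patient records.

An N-year *start* (diagnosis-year) cohort average is the mean survival of
patients diagnosed in a given calendar year who died within N calendar
years of diagnosis; it is only observable once N years of follow-up exist.
An N-year *end* (death-year) cohort average is the mean survival of
patients dying in a given calendar year who were diagnosed at most N
calendar years earlier; it is observable as soon as N years of *preceding*
diagnosis data exist, so end cohorts extend to the most recent data year.
The complementary eligibility windows are what lets the end cohorts carry
recent information that start cohorts cannot.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CohortKind = Literal["start", "end"]

__all__ = [
    "PatientRecord",
    "DataRange",
    "CohortTable",
    "CellClass",
    "SignTestResult",
    "survival_years",
    "eligible_start_cohorts",
    "eligible_end_cohorts",
    "build_cohort_table",
    "classify_cell",
    "paired_sign_test",
]


@dataclass(frozen=True)
class PatientRecord:
    """One (diagnosis year, death year) observation, optionally aggregated.

    ``count`` collapses identical rows of a registry case listing into one
    record.  Years are calendar years; real-valued years are accepted so
    that simulated records can carry unrounded survival times, but registry
    extracts use integers.
    """

    diagnosis_year: float
    death_year: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.death_year < self.diagnosis_year:
            raise ValueError(
                f"death year {self.death_year} precedes diagnosis year "
                f"{self.diagnosis_year}"
            )
        if self.count < 1:
            raise ValueError(f"count must be a positive integer, got {self.count}")


@dataclass(frozen=True)
class DataRange:
    """Inclusive span of calendar years with reliable registry coverage."""

    year_min: int
    year_max: int

    def __post_init__(self) -> None:
        if self.year_min > self.year_max:
            raise ValueError(
                f"year_min {self.year_min} exceeds year_max {self.year_max}"
            )

    def __contains__(self, year: float) -> bool:
        return self.year_min <= year <= self.year_max


class CellClass(enum.Enum):
    """Classification of a (diagnosis year, death year) cell for window N.

    The six classes partition all in-range integer pairs: cells above the
    diagonal are impossible; cells with survival beyond N fall outside the
    observation window; the remaining cells belong to an eligible diagnosis
    cohort, an eligible death cohort, both, or neither (the unused "V"
    between the two eligible regions).
    """

    START_ONLY = "start_only"
    END_ONLY = "end_only"
    BOTH = "both"
    UNUSED_V = "unused_v"
    OUT_OF_WINDOW = "out_of_window"
    INVALID = "invalid"


@dataclass(frozen=True)
class CohortTable:
    """Per-cohort-year mean survival times with patient counts.

    ``entries`` maps cohort year -> (mean survival in years, n patients),
    sorted by year.  ``omitted_years`` lists eligible cohort years that had
    no qualifying records.
    """

    kind: CohortKind
    window_N: int
    entries: dict[int, tuple[float, int]]
    omitted_years: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        years = list(self.entries)
        if years != sorted(years):
            raise ValueError("cohort entries must be sorted by year")
        for year, (mean, n) in self.entries.items():
            if not (0.0 <= mean <= self.window_N):
                raise ValueError(
                    f"cohort {year}: mean survival {mean} outside [0, {self.window_N}]"
                )
            if n < 1:
                raise ValueError(f"cohort {year}: non-positive count {n}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def years(self) -> np.ndarray:
        return np.array(list(self.entries), dtype=float)

    @property
    def means(self) -> np.ndarray:
        return np.array([m for m, _ in self.entries.values()], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([n for _, n in self.entries.values()], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort_kind": self.kind,
                "window_N": self.window_N,
                "cohort_year": list(self.entries),
                "mean_survival": [m for m, _ in self.entries.values()],
                "n": [n for _, n in self.entries.values()],
            }
        )


class SignTestResult(NamedTuple):
    n_pairs: int
    n_end_higher: int
    p_value: float


def survival_years(record: PatientRecord) -> float:
    """Survival time as the calendar-year difference death − diagnosis."""
    return record.death_year - record.diagnosis_year


def eligible_start_cohorts(data_range: DataRange, window_N: int) -> list[int]:
    """Diagnosis years with a full N years of follow-up inside the range.

    A diagnosis-year cohort's N-year average needs death data through
    year + N, so eligibility requires ``year + N <= year_max``.
    """
    _check_window(window_N)
    return [
        y
        for y in range(data_range.year_min, data_range.year_max + 1)
        if y + window_N <= data_range.year_max
    ]


def eligible_end_cohorts(data_range: DataRange, window_N: int) -> list[int]:
    """Death years with a full N years of preceding diagnosis data."""
    _check_window(window_N)
    return [
        y
        for y in range(data_range.year_min, data_range.year_max + 1)
        if y - window_N >= data_range.year_min
    ]


def _check_window(window_N: int) -> None:
    if window_N < 1:
        raise ValueError(f"window must be a positive number of years, got {window_N}")


def build_cohort_table(
    records: Iterable[PatientRecord],
    data_range: DataRange,
    window_N: int,
    kind: CohortKind,
) -> CohortTable:
    """Average survival per eligible cohort year, weighted by record counts.

    Start cohorts average over records diagnosed in the cohort year with
    survival in [0, N]; end cohorts over records dying in the cohort year
    with survival in [0, N].  Records outside the eligible cohorts (for
    example recent diagnoses whose start cohort lacks follow-up) are simply
    unused.  Eligible years with no qualifying records are reported in
    ``omitted_years``.
    """
    if kind == "start":
        eligible = eligible_start_cohorts(data_range, window_N)
    elif kind == "end":
        eligible = eligible_end_cohorts(data_range, window_N)
    else:
        raise ValueError(f"cohort kind must be 'start' or 'end', got {kind!r}")
    if not eligible:
        raise ValueError(
            f"no eligible {kind} cohort years for window {window_N} in "
            f"{data_range.year_min}-{data_range.year_max}"
        )

    records = list(records)
    diag = np.array([r.diagnosis_year for r in records], dtype=float)
    death = np.array([r.death_year for r in records], dtype=float)
    count = np.array([r.count for r in records], dtype=float)
    surv = death - diag
    in_window = (surv >= 0.0) & (surv <= window_N)
    key = diag if kind == "start" else death

    # Cohorts are grouped by the exact key values present: integer years
    # for registry extracts, real-valued years for unrounded simulated
    # records (each its own singleton cohort).  Eligibility follows the
    # same follow-up rule either way.
    if kind == "start":
        def ok(y: float) -> bool:
            return data_range.year_min <= y and y + window_N <= data_range.year_max
    else:
        def ok(y: float) -> bool:
            return y <= data_range.year_max and y - window_N >= data_range.year_min

    df = pd.DataFrame(
        {"key": key[in_window], "ws": (surv * count)[in_window], "n": count[in_window]}
    )
    grouped = df.groupby("key", sort=True).sum()
    entries: dict[float, tuple[float, int]] = {}
    for year, row in grouped.iterrows():
        if not ok(year):
            continue
        y = int(year) if float(year).is_integer() else float(year)
        entries[y] = (float(row["ws"] / row["n"]), int(row["n"]))
    omitted = tuple(y for y in eligible if y not in entries)
    if not entries:
        raise ValueError(
            f"no {kind} cohort year in {eligible[0]}-{eligible[-1]} has data"
        )
    return CohortTable(kind, window_N, entries, omitted)


def classify_cell(
    diagnosis_year: int,
    death_year: int,
    data_range: DataRange,
    window_N: int,
) -> CellClass:
    """Classify one (diagnosis year, death year) cell of the cohort grid."""
    if diagnosis_year not in data_range or death_year not in data_range:
        raise ValueError(
            f"({diagnosis_year}, {death_year}) outside data range "
            f"{data_range.year_min}-{data_range.year_max}"
        )
    if death_year < diagnosis_year:
        return CellClass.INVALID
    if death_year - diagnosis_year > window_N:
        return CellClass.OUT_OF_WINDOW
    start_ok = diagnosis_year + window_N <= data_range.year_max
    end_ok = death_year - window_N >= data_range.year_min
    if start_ok and end_ok:
        return CellClass.BOTH
    if start_ok:
        return CellClass.START_ONLY
    if end_ok:
        return CellClass.END_ONLY
    return CellClass.UNUSED_V


def paired_sign_test(
    start_table: CohortTable,
    end_table: CohortTable,
    ties: Literal["drop"] = "drop",
) -> SignTestResult:
    """One-sided exact sign test that end-cohort means exceed start means.

    The i-th eligible start year is paired positionally with the i-th
    eligible end year (the two lists have equal length whenever they come
    from the same data range and window).  Under no improvement each pair
    is a fair coin; the p-value is the exact binomial tail
    P(X >= n_end_higher | n_pairs, 1/2).  Tied pairs are dropped.
    """
    if len(start_table) != len(end_table):
        raise ValueError(
            f"cannot pair {len(start_table)} start cohorts with "
            f"{len(end_table)} end cohorts"
        )
    if ties != "drop":
        raise ValueError(f"unsupported tie policy {ties!r}")
    diffs = end_table.means - start_table.means
    diffs = diffs[diffs != 0.0]
    n_pairs = diffs.size
    n_end_higher = int((diffs > 0).sum())
    if n_pairs == 0:
        return SignTestResult(0, 0, 1.0)
    p = stats.binomtest(n_end_higher, n_pairs, 0.5, alternative="greater").pvalue
    return SignTestResult(n_pairs, n_end_higher, float(p))
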