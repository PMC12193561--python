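"""Reading and writing the package's plain-text file formats.

Records CSV: header ``diagnosis_year,death_year[,count]``; cohort-table
CSV: ``cohort_kind,window_N,cohort_year,mean_survival,n``; trend models and
fit reports as YAML/JSON key-value records.  Machine-readable outputs are
written unrounded; rounding to two decimals happens only in the headline
report.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

import yaml

from steti.cohorts import CohortTable, PatientRecord
from steti.trendmodels import TrendModel

__all__ = [
    "read_records_csv",
    "write_records_csv",
    "read_cohort_table_csv",
    "write_cohort_table_csv",
    "load_model",
    "save_model",
    "write_json_report",
]


def read_records_csv(path: str | Path) -> list[PatientRecord]:
    """Parse a registry-style case listing.

    The ``count`` column is optional and defaults to 1.  Malformed rows and
    rows with death before diagnosis are rejected with their line numbers.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    errors: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = {"diagnosis_year", "death_year"} - set(header)
        if missing:
            raise ValueError(
                f"{path}: header must contain diagnosis_year,death_year "
                f"(missing {sorted(missing)}); got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                diag = int(row["diagnosis_year"])
                death = int(row["death_year"])
                raw_count = row.get("count")
                count = int(raw_count) if raw_count not in (None, "") else 1
                records.append(PatientRecord(diag, death, count))
            except (TypeError, ValueError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} bad row(s): " + "; ".join(errors[:10]))
    return records


def write_records_csv(path: str | Path, records: Iterable[PatientRecord]) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["diagnosis_year", "death_year", "count"])
        for r in records:
            writer.writerow([r.diagnosis_year, r.death_year, r.count])


def write_cohort_table_csv(path: str | Path, table: CohortTable) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cohort_kind", "window_N", "cohort_year", "mean_survival", "n"])
        for year, (mean, n) in table.entries.items():
            writer.writerow([table.kind, table.window_N, year, repr(mean), n])


def read_cohort_table_csv(path: str | Path) -> CohortTable:
    path = Path(path)
    kinds: set[str] = set()
    windows: set[int] = set()
    entries: dict[int, tuple[float, int]] = {}
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                kinds.add(row["cohort_kind"])
                windows.add(int(row["window_N"]))
                entries[int(row["cohort_year"])] = (
                    float(row["mean_survival"]),
                    int(row["n"]),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    if len(kinds) != 1 or len(windows) != 1:
        raise ValueError(f"{path}: mixed cohort kinds {kinds} or windows {windows}")
    return CohortTable(kinds.pop(), windows.pop(), dict(sorted(entries.items())))


def save_model(path: str | Path, model: TrendModel) -> None:
    path = Path(path)
    payload = model.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> TrendModel:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return TrendModel.from_dict(payload)


def write_json_report(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
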