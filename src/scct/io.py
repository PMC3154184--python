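"""Readers and writers for the subject CSV schema and report formats.

Subject CSV: one row per subject with columns ``subject_id, group, age,
rater_id, scct1..scct14, rlt_omissions, rlt_intrusions``.  Count columns are
non-negative integers; the binary items (scct12/13/14) additionally accept
No/Yes.  ``group`` is control/patient/unknown; ``age`` and ``rater_id`` may
be empty.  Row-level problems are collected with line numbers and reported
together rather than failing at the first bad cell.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .instrument import SCCT_ITEMS
from .scoring import StandardizedRecord, SubjectRawRecord

_ITEM_COLUMNS = [f"scct{i}" for i in range(1, 15)]
_RLT_COLUMNS = ["rlt_omissions", "rlt_intrusions"]
REQUIRED_COLUMNS = ["subject_id", "group"] + _ITEM_COLUMNS
OPTIONAL_COLUMNS = ["age", "rater_id"] + _RLT_COLUMNS
_BINARY_COLUMNS = {"scct12", "scct13", "scct14"}

_COL_TO_ITEM = {f"scct{i}": f"SCCT-{i}" for i in range(1, 15)}
_COL_TO_ITEM["rlt_omissions"] = "RLT-A"
_COL_TO_ITEM["rlt_intrusions"] = "RLT-B"


class SubjectFileError(ValueError):
    """Malformed subject file; ``errors`` lists row/column-level messages."""

    def __init__(self, path, errors: list[str]):
        self.errors = errors
        joined = "\n  ".join(errors)
        super().__init__(f"{path}: {len(errors)} problem(s):\n  {joined}")


def _parse_cell(column: str, value: str, line: int, errors: list[str]):
    value = value.strip()
    if value == "":
        return None
    if column in _BINARY_COLUMNS:
        low = value.lower()
        if low in ("no", "0", "false"):
            return "No"
        if low in ("yes", "1", "true"):
            return "Yes"
        errors.append(f"line {line}, column {column}: expected No/Yes or 0/1, got {value!r}")
        return None
    try:
        n = int(value)
    except ValueError:
        errors.append(f"line {line}, column {column}: expected an integer, got {value!r}")
        return None
    if n < 0:
        errors.append(f"line {line}, column {column}: negative count {n}")
        return None
    return n


def read_subjects(path: str | Path) -> list[SubjectRawRecord]:
    """Read raw subject records, collecting all row-level errors before raising."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SubjectFileError(path, [f"header lacks required columns {missing}"])
        errors: list[str] = []
        records: list[SubjectRawRecord] = []
        for line, row in enumerate(reader, start=2):
            raw: dict = {}
            for col in _ITEM_COLUMNS + [c for c in _RLT_COLUMNS if c in header]:
                parsed = _parse_cell(col, row.get(col) or "", line, errors)
                if parsed is not None:
                    raw[_COL_TO_ITEM[col]] = parsed
            group = (row.get("group") or "unknown").strip().lower()
            if group not in ("control", "patient", "unknown"):
                errors.append(f"line {line}, column group: unknown label {row.get('group')!r}")
                continue
            age_text = (row.get("age") or "").strip()
            age = None
            if age_text:
                try:
                    age = float(age_text)
                except ValueError:
                    errors.append(f"line {line}, column age: not a number: {age_text!r}")
            records.append(
                SubjectRawRecord(
                    subject_id=(row.get("subject_id") or f"row{line}").strip(),
                    raw=raw,
                    group=group,
                    age=age,
                    rater_id=(row.get("rater_id") or "").strip() or None,
                )
            )
    if errors:
        raise SubjectFileError(path, errors)
    return records


def write_subjects(records: Sequence[SubjectRawRecord], path: str | Path) -> None:
    """Write raw records back out in the subject CSV schema (deterministic order)."""
    path = Path(path)
    columns = ["subject_id", "group", "age", "rater_id"] + _ITEM_COLUMNS + _RLT_COLUMNS
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in records:
            row = [rec.subject_id, rec.group,
                   "" if rec.age is None else rec.age,
                   rec.rater_id or ""]
            for col in _ITEM_COLUMNS + _RLT_COLUMNS:
                value = rec.raw.get(_COL_TO_ITEM[col], "")
                row.append(value)
            writer.writerow(row)


def standardized_to_frame(records: Sequence[StandardizedRecord]) -> pd.DataFrame:
    """Flatten standardized records to a deterministic tabular layout."""
    rows = []
    for rec in records:
        row: dict = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "rater_id": rec.rater_id,
        }
        row.update({k: rec.item_scores.get(k) for k in SCCT_ITEMS})
        row.update(rec.subscales)
        row.update(rec.indices)
        row["SCCT"] = rec.scct_total
        row["RLT-A"] = rec.rlt_a
        row["RLT-B"] = rec.rlt_b
        row["prorated"] = rec.prorated
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_standardized(frame: pd.DataFrame) -> list[StandardizedRecord]:
    """Rebuild standardized records from the tabular layout (round-trip of the above)."""
    records = []
    subscale_ids = ["ME", "D", "M", "R", "CI"]
    index_ids = ["DcI", "DfI", "CiI"]
    for _, row in frame.iterrows():
        records.append(
            StandardizedRecord(
                subject_id=str(row["subject_id"]),
                item_scores={k: float(row[k]) for k in SCCT_ITEMS if pd.notna(row.get(k))},
                subscales={k: float(row[k]) for k in subscale_ids},
                indices={k: float(row[k]) for k in index_ids},
                scct_total=float(row["SCCT"]),
                rlt_a=None if pd.isna(row.get("RLT-A")) else float(row["RLT-A"]),
                rlt_b=None if pd.isna(row.get("RLT-B")) else float(row["RLT-B"]),
                group=str(row.get("group", "unknown")),
                age=None if pd.isna(row.get("age")) else float(row["age"]),
                rater_id=None if pd.isna(row.get("rater_id")) else str(row["rater_id"]) or None,
                prorated=bool(row.get("prorated", False)),
            )
        )
    return records


def write_report(results, path: str | Path, format: str = "csv") -> None:
    """Write scored results (or any report object) with deterministic ordering.

    ``results`` may be a sequence of StandardizedRecords, a DataFrame, or any
    JSON-serializable object (json format only).
    """
    if results is None:
        raise ValueError("results must not be None")
    path = Path(path)
    if format == "csv":
        if isinstance(results, pd.DataFrame):
            frame = results
        else:
            frame = standardized_to_frame(list(results))
        frame.to_csv(path, index=False)
    elif format == "json":
        if isinstance(results, pd.DataFrame):
            payload = results.to_dict(orient="records")
        elif hasattr(results, "to_dict"):
            payload = results.to_dict()
        elif isinstance(results, (list, tuple)) and results and hasattr(results[0], "to_dict"):
            payload = [r.to_dict() for r in results]
        else:
            payload = results
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_ratings_matrix(path: str | Path, rater_id: str | None = None) -> pd.DataFrame:
    """Read a subjects x items ratings CSV (subject_id column + numeric item columns)."""
    frame = pd.read_csv(path)
    if "subject_id" in frame.columns:
        frame = frame.set_index("subject_id")
    drop = [c for c in ("group", "age", "rater_id", "prorated") if c in frame.columns]
    return frame.drop(columns=drop)
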