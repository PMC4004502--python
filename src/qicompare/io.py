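"""Reading and writing patient datasets as CSV and JSON.

One row per patient.  Compound items are flattened into one column per
sub-field; every item gets a ``<item>_status`` column.  Dates are ISO-8601,
procedure-code sets are ``;``-joined sorted lists.  Non-present items leave
their value columns empty.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .records import (
    COMPOUND_FIELDS,
    ITEM_NAMES,
    OPTIONAL_FLAG_ITEMS,
    DataItemValue,
    PatientRecord,
    Status,
)

_DATE_ITEMS = ("operation_date", "meeting_date", "radiotherapy_start_date")
_DATE_FIELDS = {("diagnosis", "date"), ("colonoscopy", "date")}
_BOOL_FIELDS = {
    ("diagnosis", "primary"),
    ("colonoscopy", "performed"),
    ("colonoscopy", "complete"),
    ("chemotherapy", "received"),
}


def _columns() -> list[str]:
    cols = ["patient_id", "source", "gender"]
    for item in ITEM_NAMES + OPTIONAL_FLAG_ITEMS:
        if item in COMPOUND_FIELDS:
            cols.extend(f"{item}_{fld}" for fld in COMPOUND_FIELDS[item])
        else:
            cols.append(item)
        cols.append(f"{item}_status")
    return cols


def _encode_scalar(item: str, value: Any) -> Any:
    if value is None:
        return ""
    if item == "procedure":
        return ";".join(sorted(value))
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, bool):
        return str(value).lower()
    return value


def record_to_row(record: PatientRecord) -> dict[str, Any]:
    row: dict[str, Any] = {
        "patient_id": record.patient_id,
        "source": record.source,
        "gender": record.gender,
    }
    for item, div in record.items.items():
        row[f"{item}_status"] = div.status.value
        if item in COMPOUND_FIELDS:
            payload = div.value or {}
            for fld in COMPOUND_FIELDS[item]:
                row[f"{item}_{fld}"] = _encode_scalar(item, payload.get(fld))
        else:
            row[item] = _encode_scalar(item, div.value)
    return row


def _decode_scalar(item: str, fld: str | None, raw: Any) -> Any:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    if item == "procedure":
        return set(str(raw).split(";"))
    if item in _DATE_ITEMS or (fld is not None and (item, fld) in _DATE_FIELDS):
        return dt.date.fromisoformat(str(raw))
    if item == "year_of_birth" or item == "examined_lymph_nodes":
        return int(raw)
    if item == "circumferential_margin_mm":
        return float(raw)
    if item in OPTIONAL_FLAG_ITEMS or (fld is not None and (item, fld) in _BOOL_FIELDS):
        return str(raw).lower() in ("true", "1", "yes")
    return str(raw)


def row_to_record(row: dict[str, Any]) -> PatientRecord:
    items: dict[str, DataItemValue] = {}
    for item in ITEM_NAMES + OPTIONAL_FLAG_ITEMS:
        status = Status(row.get(f"{item}_status") or "absent")
        if status is not Status.PRESENT:
            items[item] = DataItemValue(status=status)
            continue
        if item in COMPOUND_FIELDS:
            payload = {
                fld: _decode_scalar(item, fld, row.get(f"{item}_{fld}"))
                for fld in COMPOUND_FIELDS[item]
            }
            items[item] = DataItemValue(value=payload, status=status)
        else:
            items[item] = DataItemValue(value=_decode_scalar(item, None, row.get(item)), status=status)
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        source=str(row["source"]),
        gender=str(row.get("gender") or "absent"),
        items=items,
    )


def dataset_to_dataframe(dataset: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([record_to_row(r) for r in dataset], columns=_columns())


def write_dataset_csv(dataset: Sequence[PatientRecord], path: str | Path) -> None:
    dataset_to_dataframe(dataset).to_csv(path, index=False)


def read_dataset_csv(path: str | Path) -> list[PatientRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [row_to_record(row) for row in frame.to_dict(orient="records")]


def write_dataset_json(dataset: Sequence[PatientRecord], path: str | Path) -> None:
    rows = [record_to_row(r) for r in dataset]
    Path(path).write_text(json.dumps(rows, indent=1, default=str) + "\n")


def read_dataset_json(path: str | Path) -> list[PatientRecord]:
    rows = json.loads(Path(path).read_text())
    return [row_to_record(row) for row in rows]


def read_dataset(path: str | Path) -> list[PatientRecord]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_dataset_json(path)
    return read_dataset_csv(path)
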