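"""Reading and writing the three-table CSV dataset.

Schemas (UTF-8, header row mandatory, RFC-4180 quoting, ISO-8601 dates,
missing values as empty cells — never "NA"/"NULL" sentinels):

* ``practices.csv``: practice_id, vision_date, amr_date, last_collection_date
* ``patients.csv``: patient_id, practice_id, year_of_birth, gender,
  registration_date, transfer_out_date, townsend_quintile,
  pregnant_at_index, comorbidities (semicolon-joined ``name:date`` pairs)
* ``prescriptions.csv``: patient_id, date, drug_class, strength_label
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path

from .records import (
    Dataset,
    DatasetError,
    PatientRecord,
    PracticeRecord,
    PrescriptionEvent,
    SchemaError,
    VocabularyError,
)

PRACTICE_COLUMNS = ["practice_id", "vision_date", "amr_date", "last_collection_date"]
PATIENT_COLUMNS = [
    "patient_id",
    "practice_id",
    "year_of_birth",
    "gender",
    "registration_date",
    "transfer_out_date",
    "townsend_quintile",
    "pregnant_at_index",
    "comorbidities",
]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "drug_class", "strength_label"]


def _parse_date(value: str, *, context: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise SchemaError(f"{context}: bad ISO-8601 date {value!r}") from exc


def _parse_optional_date(value: str, *, context: str) -> dt.date | None:
    return _parse_date(value, context=context) if value else None


def _check_header(found: list[str] | None, expected: list[str], path: Path) -> None:
    if found is None:
        raise SchemaError(f"{path}: empty file, expected header {expected}")
    missing = [c for c in expected if c not in found]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _read_rows(path: Path, expected: list[str]):
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        _check_header(reader.fieldnames and list(reader.fieldnames), expected, path)
        yield from enumerate(reader, start=2)  # 1-based, after header


def read_practices(path: str | Path) -> dict[str, PracticeRecord]:
    path = Path(path)
    practices: dict[str, PracticeRecord] = {}
    for lineno, row in _read_rows(path, PRACTICE_COLUMNS):
        ctx = f"{path}:{lineno}"
        record = PracticeRecord(
            practice_id=row["practice_id"],
            vision_date=_parse_date(row["vision_date"], context=ctx),
            amr_date=_parse_date(row["amr_date"], context=ctx),
            last_collection_date=_parse_date(row["last_collection_date"], context=ctx),
        )
        if record.practice_id in practices:
            raise DatasetError(f"{ctx}: duplicate practice_id {record.practice_id!r}")
        practices[record.practice_id] = record
    return practices


def _parse_comorbidities(value: str, *, context: str) -> dict[str, dt.date]:
    out: dict[str, dt.date] = {}
    if not value:
        return out
    for pair in value.split(";"):
        name, sep, date_str = pair.partition(":")
        if not sep:
            raise SchemaError(f"{context}: bad comorbidity entry {pair!r}")
        if name in out:
            raise DatasetError(f"{context}: comorbidity {name!r} repeated")
        out[name] = _parse_date(date_str, context=context)
    return out


def read_patients(path: str | Path) -> dict[str, PatientRecord]:
    path = Path(path)
    patients: dict[str, PatientRecord] = {}
    for lineno, row in _read_rows(path, PATIENT_COLUMNS):
        ctx = f"{path}:{lineno}"
        try:
            year = int(row["year_of_birth"])
        except ValueError as exc:
            raise SchemaError(f"{ctx}: bad year_of_birth {row['year_of_birth']!r}") from exc
        quintile = int(row["townsend_quintile"]) if row["townsend_quintile"] else None
        pregnant_raw = row["pregnant_at_index"]
        if pregnant_raw not in ("true", "false", ""):
            raise SchemaError(f"{ctx}: pregnant_at_index must be true/false, got {pregnant_raw!r}")
        record = PatientRecord(
            patient_id=row["patient_id"],
            practice_id=row["practice_id"],
            year_of_birth=year,
            gender=row["gender"],
            registration_date=_parse_date(row["registration_date"], context=ctx),
            transfer_out_date=_parse_optional_date(row["transfer_out_date"], context=ctx),
            townsend_quintile=quintile,
            pregnant_at_index=pregnant_raw == "true",
            comorbidities=_parse_comorbidities(row["comorbidities"], context=ctx),
        )
        if record.patient_id in patients:
            raise DatasetError(f"{ctx}: duplicate patient_id {record.patient_id!r}")
        patients[record.patient_id] = record
    return patients


def read_prescriptions(path: str | Path) -> list[PrescriptionEvent]:
    path = Path(path)
    events: list[PrescriptionEvent] = []
    for lineno, row in _read_rows(path, PRESCRIPTION_COLUMNS):
        ctx = f"{path}:{lineno}"
        try:
            event = PrescriptionEvent(
                patient_id=row["patient_id"],
                date=_parse_date(row["date"], context=ctx),
                drug_class=row["drug_class"],
                strength_label=row["strength_label"],
            )
        except VocabularyError as exc:
            raise VocabularyError(f"{ctx}: {exc}") from exc
        events.append(event)
    return events


def read_dataset(
    practices_path: str | Path,
    patients_path: str | Path,
    prescriptions_path: str | Path,
) -> Dataset:
    """Load and validate the three tables into a :class:`Dataset`.

    Raises :class:`SchemaError` for missing columns or unparseable values,
    :class:`VocabularyError` for out-of-vocabulary codes (with the
    offending file and line), and :class:`ReferentialError` for dangling
    foreign keys.
    """
    return Dataset(
        practices=read_practices(practices_path),
        patients=read_patients(patients_path),
        prescriptions=read_prescriptions(prescriptions_path),
    )


def _fmt_date(value: dt.date | None) -> str:
    return value.isoformat() if value is not None else ""


def _fmt_comorbidities(comorbidities: dict[str, dt.date]) -> str:
    # Fixed name order keeps output a pure function of content.
    return ";".join(
        f"{name}:{date.isoformat()}" for name, date in sorted(comorbidities.items())
    )


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ``practices.csv``, ``patients.csv`` and ``prescriptions.csv``.

    Reading the written files reproduces the dataset field-for-field.
    Returns the three file paths keyed by table name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "practices": out_dir / "practices.csv",
        "patients": out_dir / "patients.csv",
        "prescriptions": out_dir / "prescriptions.csv",
    }

    with open(paths["practices"], "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(PRACTICE_COLUMNS)
        for p in dataset.practices.values():
            writer.writerow(
                [
                    p.practice_id,
                    p.vision_date.isoformat(),
                    p.amr_date.isoformat(),
                    p.last_collection_date.isoformat(),
                ]
            )

    with open(paths["patients"], "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(PATIENT_COLUMNS)
        for pt in dataset.patients.values():
            writer.writerow(
                [
                    pt.patient_id,
                    pt.practice_id,
                    pt.year_of_birth,
                    pt.gender,
                    pt.registration_date.isoformat(),
                    _fmt_date(pt.transfer_out_date),
                    pt.townsend_quintile if pt.townsend_quintile is not None else "",
                    "true" if pt.pregnant_at_index else "false",
                    _fmt_comorbidities(pt.comorbidities),
                ]
            )

    with open(paths["prescriptions"], "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(PRESCRIPTION_COLUMNS)
        for e in dataset.prescriptions:
            writer.writerow(
                [e.patient_id, e.date.isoformat(), e.drug_class, e.strength_label]
            )

    return paths


def load_dataset_dir(data_dir: str | Path) -> Dataset:
    """Convenience: read a directory produced by :func:`write_dataset`."""
    data_dir = Path(data_dir)
    return read_dataset(
        data_dir / "practices.csv",
        data_dir / "patients.csv",
        data_dir / "prescriptions.csv",
    )
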