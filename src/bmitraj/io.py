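"""CSV schemas and readers/writers for cohort data and pipeline artifacts.

All files are UTF-8 CSVs with fixed documented headers; units are kg, cm
and months throughout.

* ``subjects.csv`` — subject_id, sex, birth_weight_kg (plus any exposure
  flag columns).
* ``exams.csv`` — subject_id, exam_index (1-7), age_months, height_cm,
  weight_kg; missing exams are simply absent as rows.
* ``truth.csv`` — simulator ground truth (see :mod:`bmitraj.synth`).

Malformed rows are routed to a reject frame with their 1-based file line
number and a reason; they are never silently dropped.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .qc import ExamMeasurement, InputError, SubjectRecord
from .synth import EXAM_AGES_MONTHS

__all__ = [
    "SchemaError",
    "SUBJECT_COLUMNS",
    "EXAM_COLUMNS",
    "read_subjects_csv",
    "read_exams_csv",
    "load_cohort",
    "build_records",
    "write_cohort",
    "write_clean_cohort",
    "read_clean_cohort",
    "write_frame",
    "manifest",
]

SUBJECT_COLUMNS = ("subject_id", "sex", "birth_weight_kg")
EXAM_COLUMNS = ("subject_id", "exam_index", "age_months", "height_cm", "weight_kg")

_SEXES = {"male", "female"}


class SchemaError(InputError):
    """A file is missing mandatory columns."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")


def _line_numbers(df: pd.DataFrame) -> pd.Series:
    # header occupies line 1
    return pd.Series(df.index + 2, index=df.index, name="line")


def read_subjects_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a subjects table; returns ``(subjects, rejects)``.

    Rows with an unknown sex or a non-numeric birth weight are rejected.
    A birth weight that is merely out of range is kept — that is a QC
    decision, not a parse error.
    """
    df = pd.read_csv(path, dtype={"subject_id": str},
                     float_precision="round_trip")
    _require_columns(df, SUBJECT_COLUMNS, path)
    lines = _line_numbers(df)
    bw = pd.to_numeric(df["birth_weight_kg"], errors="coerce")
    bad_sex = ~df["sex"].isin(_SEXES)
    bad_bw = bw.isna() & df["birth_weight_kg"].notna()
    bad_id = df["subject_id"].isna() | (df["subject_id"].astype(str).str.len() == 0)
    dup = df["subject_id"].duplicated(keep="first")
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[bad_bw] = "non_numeric_birth_weight"
    reasons[bad_sex] = "unknown_sex"
    reasons[bad_id] = "missing_subject_id"
    reasons[dup & (reasons == "")] = "duplicate_subject_id"
    bad = reasons != ""
    rejects = df.loc[bad].assign(line=lines[bad], reason=reasons[bad])
    good = df.loc[~bad].copy()
    good["birth_weight_kg"] = bw[~bad]
    return good.reset_index(drop=True), rejects.reset_index(drop=True)


def read_exams_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an exams table; returns ``(exams, rejects)``.

    Rejected rows: non-numeric measurements, non-positive heights/weights,
    exam_index outside 1-7, duplicate (subject, exam) pairs.
    """
    df = pd.read_csv(path, dtype={"subject_id": str},
                     float_precision="round_trip")
    _require_columns(df, EXAM_COLUMNS, path)
    lines = _line_numbers(df)
    idx = pd.to_numeric(df["exam_index"], errors="coerce")
    age = pd.to_numeric(df["age_months"], errors="coerce")
    h = pd.to_numeric(df["height_cm"], errors="coerce")
    w = pd.to_numeric(df["weight_kg"], errors="coerce")
    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[(h.isna() & df["height_cm"].notna()) |
            (w.isna() & df["weight_kg"].notna())] = "non_numeric_measurement"
    reasons[(h <= 0) | (w <= 0)] = "non_positive_measurement"
    reasons[idx.isna() | ~idx.isin(range(1, 8)) | age.isna()] = "bad_exam_index_or_age"
    dup = df.duplicated(subset=["subject_id", "exam_index"], keep="first")
    reasons[dup & (reasons == "")] = "duplicate_exam"
    bad = reasons != ""
    rejects = df.loc[bad].assign(line=lines[bad], reason=reasons[bad])
    good = df.loc[~bad].copy()
    good["exam_index"] = idx[~bad].astype(int)
    good["age_months"] = age[~bad]
    good["height_cm"] = h[~bad]
    good["weight_kg"] = w[~bad]
    return good.reset_index(drop=True), rejects.reset_index(drop=True)


def build_records(subjects: pd.DataFrame, exams: pd.DataFrame,
                  exam_ages: Sequence[float] = EXAM_AGES_MONTHS,
                  ) -> list[SubjectRecord]:
    """Assemble :class:`SubjectRecord` objects from the two tables.

    Every subject gets a full slate of exam slots; slots without a row are
    present with missing measurements.  Exam rows whose subject does not
    appear in the subjects table raise.
    """
    known = set(subjects["subject_id"])
    orphans = set(exams["subject_id"]) - known
    if orphans:
        raise InputError(f"exam rows for unknown subjects: {sorted(orphans)[:5]}...")
    by_subject: dict[str, dict[int, tuple]] = {sid: {} for sid in known}
    for row in exams.itertuples(index=False):
        by_subject[row.subject_id][int(row.exam_index)] = (
            float(row.height_cm), float(row.weight_kg))
    records = []
    for row in subjects.itertuples(index=False):
        slots = by_subject[row.subject_id]
        exam_list = []
        for i, a in enumerate(exam_ages, start=1):
            hw = slots.get(i)
            exam_list.append(ExamMeasurement(
                exam_index=i, age_months=float(a),
                height_cm=hw[0] if hw else None,
                weight_kg=hw[1] if hw else None))
        bw = row.birth_weight_kg
        records.append(SubjectRecord(
            id=row.subject_id, sex=row.sex,
            birth_weight_kg=float(bw) if pd.notna(bw) else None,
            exams=exam_list))
    return records


def load_cohort(subjects_path, exams_path,
                exam_ages: Sequence[float] = EXAM_AGES_MONTHS,
                ) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Read both CSVs and assemble records; returns ``(cohort, rejects)``."""
    subjects, rej_s = read_subjects_csv(subjects_path)
    exams, rej_e = read_exams_csv(exams_path)
    # exams of rejected subjects would otherwise look orphaned
    exams = exams[exams["subject_id"].isin(set(subjects["subject_id"]))]
    rejects = pd.concat([rej_s.assign(file="subjects"),
                         rej_e.assign(file="exams")], ignore_index=True)
    return build_records(subjects, exams, exam_ages), rejects


def write_frame(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    return path


def write_cohort(out_dir, subjects: pd.DataFrame, exams: pd.DataFrame,
                 truth: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write simulator output tables into ``out_dir``."""
    out = Path(out_dir)
    paths = {"subjects": write_frame(subjects, out / "subjects.csv"),
             "exams": write_frame(exams, out / "exams.csv")}
    if truth is not None:
        paths["truth"] = write_frame(truth, out / "truth.csv")
    return paths


def write_clean_cohort(out_dir, clean: Iterable[SubjectRecord]) -> dict[str, Path]:
    """Write a QC-passed cohort (with validity flags) for downstream stages."""
    from .qc import cohort_frame

    clean = list(clean)
    out = Path(out_dir)
    subjects = pd.DataFrame(
        [(s.id, s.sex, s.birth_weight_kg) for s in clean],
        columns=list(SUBJECT_COLUMNS))
    exams = cohort_frame(clean).drop(columns=["sex", "birth_weight_kg"])
    return {"subjects_clean": write_frame(subjects, out / "subjects_clean.csv"),
            "exams_clean": write_frame(exams, out / "exams_clean.csv")}


def read_clean_cohort(directory) -> list[SubjectRecord]:
    """Rebuild a clean cohort written by :func:`write_clean_cohort`."""
    d = Path(directory)
    subjects = pd.read_csv(d / "subjects_clean.csv", dtype={"subject_id": str},
                           float_precision="round_trip")
    exams = pd.read_csv(d / "exams_clean.csv", dtype={"subject_id": str},
                        float_precision="round_trip")
    _require_columns(subjects, SUBJECT_COLUMNS, d / "subjects_clean.csv")
    _require_columns(exams, ("subject_id", "exam_index", "age_months",
                             "height_cm", "weight_kg", "valid",
                             "invalid_reason"), d / "exams_clean.csv")
    by_subject: dict[str, list[ExamMeasurement]] = {}
    for row in exams.itertuples(index=False):
        by_subject.setdefault(row.subject_id, []).append(ExamMeasurement(
            exam_index=int(row.exam_index), age_months=float(row.age_months),
            height_cm=None if pd.isna(row.height_cm) else float(row.height_cm),
            weight_kg=None if pd.isna(row.weight_kg) else float(row.weight_kg),
            valid=bool(row.valid), invalid_reason=str(row.invalid_reason)))
    records = []
    for row in subjects.itertuples(index=False):
        exam_list = sorted(by_subject.get(row.subject_id, []),
                           key=lambda e: e.exam_index)
        records.append(SubjectRecord(
            id=row.subject_id, sex=row.sex,
            birth_weight_kg=float(row.birth_weight_kg),
            exams=exam_list, included=True))
    return records


def manifest(paths: Iterable[Path]) -> dict[str, str]:
    """SHA-256 digest per file, keyed by file name."""
    out = {}
    for p in paths:
        p = Path(p)
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
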