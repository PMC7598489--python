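"""Record- and subject-level quality control for longitudinal check-up data.

Filters applied, in order:

* subjects with a birth weight outside [0.5, 5.0] kg (or missing) are
  excluded outright;
* within a subject, each exam is valid only if both measurements are
  present, height >= 25 cm, weight >= birth weight, and both have strictly
  increased relative to the most recent previously *valid* exam (for exam I
  the floors themselves act as the baseline);
* subjects with fewer than 5 valid exams out of 7 are excluded.

An invalid exam never becomes the comparison baseline for later exams, so a
single corrupted record cannot poison the rest of the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "HEIGHT_FLOOR_CM",
    "MIN_VALID_EXAMS",
    "BIRTH_WEIGHT_RANGE_KG",
    "ExamMeasurement",
    "SubjectRecord",
    "QCReport",
    "check_birth_weight",
    "compute_bmi",
    "validate_sequence",
    "apply_qc",
    "cohort_frame",
]

HEIGHT_FLOOR_CM = 25.0
MIN_VALID_EXAMS = 5
BIRTH_WEIGHT_RANGE_KG = (0.5, 5.0)

#: invalid_reason values, in rule-evaluation order.
INVALID_REASONS = ("missing", "height_below_min", "weight_below_birth",
                   "height_not_increased", "weight_not_increased")
EXCLUSION_REASONS = ("birth_weight_out_of_range", "fewer_than_5_valid")


class InputError(ValueError):
    """Raised for malformed or precondition-violating inputs."""


@dataclass
class ExamMeasurement:
    """One check-up record; ``height_cm``/``weight_kg`` may be None (missing)."""

    exam_index: int
    age_months: float
    height_cm: float | None = None
    weight_kg: float | None = None
    valid: bool = False
    invalid_reason: str = "none"

    @property
    def present(self) -> bool:
        return (self.height_cm is not None and self.weight_kg is not None
                and math.isfinite(self.height_cm) and math.isfinite(self.weight_kg))


@dataclass
class SubjectRecord:
    """One child's identity, birth weight and ordered exam sequence."""

    id: str
    sex: str
    birth_weight_kg: float | None
    exams: list[ExamMeasurement] = field(default_factory=list)
    included: bool = False
    exclusion_reason: str = "none"

    @property
    def n_valid(self) -> int:
        return sum(e.valid for e in self.exams)

    def exam(self, index: int) -> ExamMeasurement | None:
        for e in self.exams:
            if e.exam_index == index:
                return e
        return None


@dataclass
class QCReport:
    """Exclusion accounting; always partitions the input cohort exactly."""

    n_input: int
    n_excluded_birth_weight: int
    n_excluded_too_few_valid: int
    n_included: int
    invalid_record_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parts = (self.n_excluded_birth_weight, self.n_excluded_too_few_valid,
                 self.n_included)
        if any(c < 0 for c in (self.n_input, *parts)):
            raise ValueError("QC counts must be non-negative")
        if sum(parts) != self.n_input:
            raise ValueError("QC report does not partition the input cohort")

    def to_dict(self) -> dict:
        d = {"n_input": self.n_input,
             "n_excluded_birth_weight": self.n_excluded_birth_weight,
             "n_excluded_too_few_valid": self.n_excluded_too_few_valid,
             "n_included": self.n_included}
        d.update({f"invalid_{k}": v for k, v in self.invalid_record_counts.items()})
        return d


def check_birth_weight(w0) -> bool:
    """True iff ``w0`` lies in the inclusive range 0.5-5.0 kg."""
    if w0 is None:
        raise InputError("birth weight is missing")
    try:
        w0 = float(w0)
    except (TypeError, ValueError) as exc:
        raise InputError(f"non-numeric birth weight: {w0!r}") from exc
    if not math.isfinite(w0):
        raise InputError(f"non-finite birth weight: {w0!r}")
    lo, hi = BIRTH_WEIGHT_RANGE_KG
    return lo <= w0 <= hi


def compute_bmi(height_cm, weight_kg):
    """BMI in kg/m^2 from height in cm and weight in kg.

    Accepts scalars or arrays; raises on non-positive heights.
    """
    h = np.asarray(height_cm, dtype=float)
    if np.any(h <= 0):
        raise ValueError("height must be positive")
    bmi = np.asarray(weight_kg, dtype=float) / (h / 100.0) ** 2
    if np.ndim(height_cm) == 0 and np.ndim(weight_kg) == 0:
        return float(bmi)
    return bmi


def validate_sequence(subject: SubjectRecord, strict: bool = True) -> SubjectRecord:
    """Set validity flags on a subject's exams in place (and return it).

    ``strict`` controls whether "increased" means strictly greater (default)
    or greater-or-equal.  The first failing rule, in the order missing /
    height_below_min / weight_below_birth / height_not_increased /
    weight_not_increased, is recorded as ``invalid_reason``.
    """
    indices = [e.exam_index for e in subject.exams]
    if indices != sorted(indices) or len(set(indices)) != len(indices):
        raise InputError(f"subject {subject.id}: exams not sorted or duplicated")
    if subject.birth_weight_kg is None or not math.isfinite(subject.birth_weight_kg):
        raise InputError(f"subject {subject.id}: birth weight unavailable")

    w0 = float(subject.birth_weight_kg)
    increased = (lambda x, prev: x > prev) if strict else (lambda x, prev: x >= prev)
    last_valid_height: float | None = None
    last_valid_weight: float | None = None
    for e in subject.exams:
        e.valid = False
        if not e.present:
            e.invalid_reason = "missing"
        elif e.height_cm < HEIGHT_FLOOR_CM:
            e.invalid_reason = "height_below_min"
        elif e.weight_kg < w0:
            e.invalid_reason = "weight_below_birth"
        elif last_valid_height is not None and not increased(e.height_cm, last_valid_height):
            e.invalid_reason = "height_not_increased"
        elif last_valid_weight is not None and not increased(e.weight_kg, last_valid_weight):
            e.invalid_reason = "weight_not_increased"
        else:
            e.valid = True
            e.invalid_reason = "none"
            last_valid_height = e.height_cm
            last_valid_weight = e.weight_kg
    return subject


def apply_qc(cohort: list[SubjectRecord], strict: bool = True
             ) -> tuple[list[SubjectRecord], QCReport]:
    """Run both subject filters over a cohort.

    Returns the included subjects (with validity flags set) and a
    :class:`QCReport` that accounts for every input subject.  An empty
    cohort yields an empty clean cohort and a zeroed report.
    """
    clean: list[SubjectRecord] = []
    n_bw = 0
    n_few = 0
    invalid_counts = {r: 0 for r in INVALID_REASONS}
    for s in cohort:
        try:
            bw_ok = check_birth_weight(s.birth_weight_kg)
        except InputError:
            bw_ok = False
        if not bw_ok:
            s.included = False
            s.exclusion_reason = "birth_weight_out_of_range"
            n_bw += 1
            continue
        validate_sequence(s, strict=strict)
        for e in s.exams:
            if not e.valid:
                invalid_counts[e.invalid_reason] += 1
        if s.n_valid >= MIN_VALID_EXAMS:
            s.included = True
            s.exclusion_reason = "none"
            clean.append(s)
        else:
            s.included = False
            s.exclusion_reason = "fewer_than_5_valid"
            n_few += 1
    report = QCReport(n_input=len(cohort), n_excluded_birth_weight=n_bw,
                      n_excluded_too_few_valid=n_few, n_included=len(clean),
                      invalid_record_counts=invalid_counts)
    return clean, report


def cohort_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format frame of a (clean) cohort with BMI on valid exams.

    One row per subject x exam slot, columns: subject_id, sex,
    birth_weight_kg, exam_index, age_months, height_cm, weight_kg, valid,
    invalid_reason, bmi (NaN on invalid exams).
    """
    rows = []
    for s in subjects:
        for e in s.exams:
            bmi = (compute_bmi(e.height_cm, e.weight_kg)
                   if e.valid else float("nan"))
            rows.append((s.id, s.sex, s.birth_weight_kg, e.exam_index,
                         e.age_months,
                         e.height_cm if e.height_cm is not None else float("nan"),
                         e.weight_kg if e.weight_kg is not None else float("nan"),
                         e.valid, e.invalid_reason, bmi))
    return pd.DataFrame(rows, columns=[
        "subject_id", "sex", "birth_weight_kg", "exam_index", "age_months",
        "height_cm", "weight_kg", "valid", "invalid_reason", "bmi"])
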