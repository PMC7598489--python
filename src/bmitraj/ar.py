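"""Adiposity-rebound (AR) timing: nadir detection, classification, prevalence.

The nadir is the exam with the lowest valid BMI; AR timing classes are

* ``very_early``       — nadir at exams I-V (up to 45 months),
* ``early``            — nadir at exam VI (57 months),
* ``moderate_to_late`` — nadir at exam VII (69 months),
* ``unclassified``     — nadir not identifiable.

By default a nadir is unidentifiable when exam VII is missing or invalid:
without the final observation a rebound cannot be distinguished from a
still-falling trajectory.  The predicate is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import InputError, SubjectRecord, compute_bmi

__all__ = [
    "AR_CLASSES",
    "NadirResult",
    "find_nadir",
    "classify_ar",
    "classify_cohort",
    "prevalence",
    "PrevalenceTable",
    "prevalence_from_counts",
    "cumulative_percent",
]

AR_CLASSES = ("very_early", "early", "moderate_to_late")
UNCLASSIFIED = "unclassified"

LAST_EXAM_INDEX = 7
VERY_EARLY_MAX_EXAM = 5  # exams I-V inclusive
EARLY_EXAM = 6


@dataclass(frozen=True)
class NadirResult:
    subject_id: str
    nadir_exam: int | None  # None when unidentifiable
    nadir_bmi: float | None
    tie: bool


def _exam7_valid(subject: SubjectRecord, argmin_exam: int) -> bool:
    last = subject.exam(LAST_EXAM_INDEX)
    return last is not None and last.valid


def find_nadir(subject: SubjectRecord, tie: str = "earliest",
               identifiable: Callable[[SubjectRecord, int], bool] = _exam7_valid,
               ) -> NadirResult:
    """Locate the minimum-BMI exam of a QC-passed subject.

    Ties are broken to the earliest tying exam by default (``tie="latest"``
    selects the last) and flagged either way.  ``identifiable`` decides
    whether a located argmin counts as an observed rebound; the default
    requires a valid exam VII.
    """
    if tie not in ("earliest", "latest"):
        raise ValueError(f"tie must be 'earliest' or 'latest', got {tie!r}")
    if not subject.included:
        raise InputError(f"subject {subject.id} has not passed QC")
    valid = [(e.exam_index, compute_bmi(e.height_cm, e.weight_kg))
             for e in subject.exams if e.valid]
    bmis = [b for _, b in valid]
    lowest = min(bmis)
    tying = [idx for idx, b in valid if b == lowest]
    nadir_exam = tying[0] if tie == "earliest" else tying[-1]
    is_tie = len(tying) > 1
    if not identifiable(subject, nadir_exam):
        return NadirResult(subject.id, None, None, is_tie)
    return NadirResult(subject.id, nadir_exam, lowest, is_tie)


def classify_ar(nadir: NadirResult) -> str:
    """Map a nadir exam to its AR timing class."""
    if nadir.nadir_exam is None:
        return UNCLASSIFIED
    if nadir.nadir_exam <= VERY_EARLY_MAX_EXAM:
        return "very_early"
    if nadir.nadir_exam == EARLY_EXAM:
        return "early"
    return "moderate_to_late"


def classify_cohort(clean: Iterable[SubjectRecord], tie: str = "earliest",
                    identifiable: Callable[[SubjectRecord, int], bool] = _exam7_valid,
                    ) -> pd.DataFrame:
    """Per-subject classification table for a clean cohort.

    Columns: subject_id, sex, nadir_exam (nullable Int64), nadir_bmi, tie,
    ar_class.
    """
    rows = []
    for s in clean:
        n = find_nadir(s, tie=tie, identifiable=identifiable)
        rows.append((s.id, s.sex, n.nadir_exam, n.nadir_bmi, n.tie,
                     classify_ar(n)))
    df = pd.DataFrame(rows, columns=["subject_id", "sex", "nadir_exam",
                                     "nadir_bmi", "tie", "ar_class"])
    df["nadir_exam"] = df["nadir_exam"].astype("Int64")
    return df


@dataclass
class PrevalenceTable:
    """Per-exam nadir-timing prevalence, total and by sex, with cumulatives.

    ``table`` has one row per exam index and, for each of the total/male/
    female columns, the count, the percentage over that column's classified
    denominator, and the running cumulative percentage.
    """

    table: pd.DataFrame
    n_classified: int
    n_unclassified: int

    @property
    def class_counts(self) -> dict[str, int]:
        t = self.table
        return {
            "very_early": int(t.loc[t.index <= VERY_EARLY_MAX_EXAM, "n_total"].sum()),
            "early": int(t.loc[EARLY_EXAM, "n_total"]),
            "moderate_to_late": int(t.loc[LAST_EXAM_INDEX, "n_total"]),
        }

    def class_prevalence(self, ndigits: int | None = 1) -> dict[str, float]:
        return prevalence_from_counts(self.class_counts, ndigits=ndigits)


def prevalence(classified: pd.DataFrame,
               exam_ages: Sequence[float] | None = None) -> PrevalenceTable:
    """Build the prevalence table from a :func:`classify_cohort` frame.

    Unclassified subjects are excluded from every denominator.  Raises if no
    subject is classified.
    """
    known = classified[classified["ar_class"] != UNCLASSIFIED]
    if len(known) == 0:
        raise ValueError("no classified subjects; prevalence table is empty")
    exams = pd.Index(range(1, LAST_EXAM_INDEX + 1), name="exam_index")
    out = pd.DataFrame(index=exams)
    if exam_ages is not None:
        out["age_months"] = list(exam_ages)
    groups = {"total": known, "male": known[known["sex"] == "male"],
              "female": known[known["sex"] == "female"]}
    for name, g in groups.items():
        counts = g["nadir_exam"].value_counts().reindex(exams, fill_value=0)
        out[f"n_{name}"] = counts.astype(int)
        denom = len(g)
        pct = (100.0 * counts / denom) if denom else counts * np.nan
        out[f"pct_{name}"] = pct
        out[f"cum_pct_{name}"] = cumulative_percent(pct.to_numpy())
    return PrevalenceTable(table=out, n_classified=len(known),
                           n_unclassified=int(len(classified) - len(known)))


def prevalence_from_counts(counts: Mapping[str, int],
                           ndigits: int | None = 1) -> dict[str, float]:
    """Percentages of each group over the total of ``counts``.

    Rounded to ``ndigits`` decimals (None for unrounded); the accounting
    primitive behind every printed prevalence figure.
    """
    total = 0
    for k, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for {k!r}")
        total += c
    if total == 0:
        raise ValueError("zero total count")
    out = {}
    for k, c in counts.items():
        p = 100.0 * c / total
        out[k] = round(p, ndigits) if ndigits is not None else p
    return out


def cumulative_percent(values) -> np.ndarray:
    """Running sum of per-level percentages (non-decreasing for >=0 input)."""
    return np.cumsum(np.asarray(values, dtype=float))
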