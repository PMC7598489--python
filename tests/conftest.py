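import numpy as np
import pytest

from bmitraj.qc import ExamMeasurement, SubjectRecord, apply_qc
from bmitraj.synth import EXAM_AGES_MONTHS, SimConfig, generate_cohort
from bmitraj.io import build_records


def make_subject(heights, weights, w0=3.2, sex="male", sid="S1"):
    """Build a SubjectRecord from parallel height/weight lists (None = missing)."""
    exams = []
    for i, (h, w) in enumerate(zip(heights, weights), start=1):
        exams.append(ExamMeasurement(exam_index=i,
                                     age_months=EXAM_AGES_MONTHS[i - 1],
                                     height_cm=h, weight_kg=w))
    return SubjectRecord(id=sid, sex=sex, birth_weight_kg=w0, exams=exams)


def subject_with_bmis(bmis, w0=3.2, sex="male", sid="S1"):
    """Subject whose valid-exam BMIs equal ``bmis`` exactly (None = missing).

    Heights increase steadily so the record passes every QC rule whenever
    the implied weights do.  Heights 100/106 are chosen so that equal BMIs
    at exams V/VI survive the weight->BMI float round trip bit-exactly.
    """
    heights = [60, 70, 80, 90, 100, 106, 112]
    weights = [None if b is None else b * (h / 100.0) ** 2
               for b, h in zip(bmis, heights)]
    heights = [None if b is None else h for b, h in zip(bmis, heights)]
    return make_subject(heights, weights, w0=w0, sex=sex, sid=sid)


@pytest.fixture(scope="session")
def pristine_cohort():
    """Noise-free, corruption-free simulated cohort (tables + records)."""
    cfg = SimConfig(n_subjects=500, seed=42, noise_height_sd=0.0,
                    noise_weight_sd=0.0)
    subjects, exams, truth = generate_cohort(cfg)
    return subjects, exams, truth


@pytest.fixture(scope="session")
def clean_records(pristine_cohort):
    subjects, exams, _ = pristine_cohort
    clean, report = apply_qc(build_records(subjects, exams))
    return clean, report


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
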