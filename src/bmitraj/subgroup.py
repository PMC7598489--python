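"""Subject-level subgroup labels: birth-weight class, rapid weight gain,
and BMI status at exam VI.

Boundary conventions (all inclusive/exclusive exactly as stated):

* birth-weight classes partition [0.5, 5.0] kg as
  VLBW [0.5, 1.5], LBW (1.5, 2.5], non-LBW (2.5, 5.0];
* rapid weight gain: birth-to-exam-I gain >= threshold (default 5.1 kg);
* BMI status at exam VI: underweight < P5 <= normal < P85 <= overweight
  < P95 <= obese, with sex-specific thresholds.

BMI-status thresholds default to within-cohort empirical percentiles
(stratified by sex) but an external sex x percentile table may be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import InputError, SubjectRecord, compute_bmi

__all__ = [
    "BIRTH_WEIGHT_CLASSES",
    "BMI_STATUS_LEVELS",
    "RWG_THRESHOLD_KG",
    "RWGStatus",
    "classify_birth_weight",
    "classify_rwg",
    "derive_rwg_threshold",
    "empirical_percentiles",
    "classify_bmi_status",
    "bmi_status_thresholds",
    "assign_subgroups",
    "rwg_prevalence",
    "load_threshold_table",
]

BIRTH_WEIGHT_CLASSES = ("VLBW", "LBW", "non_LBW")
BMI_STATUS_LEVELS = ("underweight", "normal", "overweight", "obese")
BMI_STATUS_PERCENTILES = (5.0, 85.0, 95.0)
RWG_THRESHOLD_KG = 5.1
BMI_STATUS_EXAM = 6


@dataclass(frozen=True)
class RWGStatus:
    rapid: bool
    delta_w: float
    threshold: float


def classify_birth_weight(w0: float) -> str:
    """Map a QC-passed birth weight (kg) to VLBW / LBW / non_LBW."""
    if not 0.5 <= w0 <= 5.0:
        raise InputError(f"birth weight {w0} outside [0.5, 5.0] kg; "
                         "should have been excluded by QC")
    if w0 <= 1.5:
        return "VLBW"
    if w0 <= 2.5:
        return "LBW"
    return "non_LBW"


def classify_rwg(w0: float, w_exam1: float,
                 threshold: float = RWG_THRESHOLD_KG) -> RWGStatus:
    """Rapid-weight-gain status from birth and exam-I weights (kg).

    Rapid iff the gain is >= ``threshold`` (boundary inclusive).
    """
    if w_exam1 < w0:
        raise InputError("exam-I weight below birth weight; invalid record")
    delta = w_exam1 - w0
    return RWGStatus(rapid=delta >= threshold, delta_w=delta, threshold=threshold)


def derive_rwg_threshold(mean_birth: float, mean_5mo: float, sd_5mo: float,
                         z_change: float = 0.67) -> float:
    """Weight gain that lifts a median-born child by ``z_change`` z at 5 months.

    ``(mean_5mo + z_change * sd_5mo) - mean_birth`` given a reference
    providing the weight mean at birth and mean/SD at 5 months.
    """
    for name, v in (("mean_birth", mean_birth), ("mean_5mo", mean_5mo),
                    ("sd_5mo", sd_5mo)):
        if v is None or not np.isfinite(v):
            raise InputError(f"reference field {name} is missing")
    if sd_5mo < 0:
        raise InputError("sd_5mo must be non-negative")
    return (mean_5mo + z_change * sd_5mo) - mean_birth


def empirical_percentiles(values, probs) -> np.ndarray:
    """Empirical quantiles at percentile levels ``probs`` (linear interpolation).

    Uses linear interpolation between order statistics (the Hyndman-Fan
    "type 7" convention, numpy's default).  Requires at least two finite
    values; returns thresholds non-decreasing in ``probs``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise InputError("need at least two finite values for percentiles")
    p = np.asarray(probs, dtype=float)
    if np.any((p <= 0) | (p >= 100)):
        raise InputError("percentile levels must lie strictly inside (0, 100)")
    return np.quantile(v, p / 100.0, method="linear")


def classify_bmi_status(bmi: float, thresholds: Sequence[float]) -> str:
    """Map a BMI to its status given (P5, P85, P95) thresholds."""
    p5, p85, p95 = thresholds
    if not (p5 <= p85 <= p95):
        raise InputError("thresholds must be non-decreasing (P5 <= P85 <= P95)")
    if bmi < p5:
        return "underweight"
    if bmi < p85:
        return "normal"
    if bmi < p95:
        return "overweight"
    return "obese"


def bmi_status_thresholds(bmi_by_sex: Mapping[str, Sequence[float]]
                          ) -> dict[str, tuple[float, float, float]]:
    """Within-cohort sex-specific (P5, P85, P95) thresholds."""
    return {sex: tuple(empirical_percentiles(v, BMI_STATUS_PERCENTILES))
            for sex, v in bmi_by_sex.items()}


def load_threshold_table(path) -> dict[str, tuple[float, float, float]]:
    """Read an external threshold CSV with columns sex, percentile, bmi."""
    df = pd.read_csv(path)
    missing = {"sex", "percentile", "bmi"} - set(df.columns)
    if missing:
        raise InputError(f"threshold table missing columns: {sorted(missing)}")
    out = {}
    for sex, g in df.groupby("sex"):
        g = g.set_index("percentile")["bmi"]
        try:
            out[str(sex)] = tuple(float(g.loc[p]) for p in BMI_STATUS_PERCENTILES)
        except KeyError as exc:
            raise InputError(f"threshold table lacks percentile {exc} for {sex}")
    return out


def assign_subgroups(clean: Iterable[SubjectRecord],
                     rwg_threshold: float = RWG_THRESHOLD_KG,
                     thresholds: Mapping[str, Sequence[float]] | None = None,
                     ) -> pd.DataFrame:
    """Subject-level subgroup table for a clean cohort.

    Columns: subject_id, sex, birth_weight_kg, bw_class, delta_w_5mo, rwg,
    bmi_exam6, bmi_status.  ``rwg`` is NA when exam I is invalid and
    ``bmi_status`` is NA when exam VI is invalid.  When ``thresholds`` is
    None, sex-stratified within-cohort percentiles at exam VI are used.
    """
    clean = list(clean)
    rows = []
    for s in clean:
        bw_class = classify_birth_weight(float(s.birth_weight_kg))
        e1 = s.exam(1)
        if e1 is not None and e1.valid:
            status = classify_rwg(float(s.birth_weight_kg), e1.weight_kg,
                                  threshold=rwg_threshold)
            delta_w, rapid = status.delta_w, status.rapid
        else:
            delta_w, rapid = float("nan"), pd.NA
        e6 = s.exam(BMI_STATUS_EXAM)
        bmi6 = (compute_bmi(e6.height_cm, e6.weight_kg)
                if e6 is not None and e6.valid else float("nan"))
        rows.append((s.id, s.sex, s.birth_weight_kg, bw_class, delta_w,
                     rapid, bmi6))
    df = pd.DataFrame(rows, columns=["subject_id", "sex", "birth_weight_kg",
                                     "bw_class", "delta_w_5mo", "rwg",
                                     "bmi_exam6"])
    df["rwg"] = df["rwg"].astype("boolean")

    if thresholds is None:
        by_sex = {sex: g["bmi_exam6"].dropna().to_numpy()
                  for sex, g in df.groupby("sex")}
        thresholds = bmi_status_thresholds(by_sex)

    def status(row):
        if not np.isfinite(row["bmi_exam6"]):
            return pd.NA
        return classify_bmi_status(row["bmi_exam6"], thresholds[row["sex"]])

    df["bmi_status"] = df.apply(status, axis=1) if len(df) else pd.Series(dtype=object)
    return df


def rwg_prevalence(n_rapid: int, n_total: int, ndigits: int | None = 1) -> float:
    """Percentage of rapid gainers among ``n_total`` subjects."""
    if n_total <= 0:
        raise InputError("n_total must be positive")
    if not 0 <= n_rapid <= n_total:
        raise InputError("n_rapid must lie in [0, n_total]")
    p = 100.0 * n_rapid / n_total
    return round(p, ndigits) if ndigits is not None else p
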