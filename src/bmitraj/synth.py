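"""Synthetic check-up cohort generation.

Simulates longitudinal infant health check-up data with the structure the
downstream pipeline assumes: each child follows a smooth BMI curve with an
infancy peak, a mid-childhood nadir and a post-nadir rebound, on top of a
monotone Jenss-Bayley height curve.  The generator also injects measurement
noise, missing exams and corrupted (non-increasing or out-of-range) records,
and emits a per-child ground-truth table so that quality-control and
nadir-detection code can be validated against known answers.

The per-child BMI curve is piecewise quadratic in age ``t`` (months)::

    B(t) = B_peak - (B_peak - B0) * ((t_peak - t) / t_peak)**2      t <  t_peak
    B(t) = B_R + (B_peak - B_R) * ((t_R - t) / (t_R - t_peak))**2   t_peak <= t < t_R
    B(t) = B_R + k_reb * (t - t_R)**2                               t >= t_R

which guarantees a single interior minimum at ``t_R`` and continuity at the
branch boundaries.  Height follows the classical Jenss-Bayley form
``h(t) = A + B_h*t - C_h*exp(-D_h*t)`` and weight is derived from BMI and
height, so all three measurements are mutually consistent.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EXAM_AGES_MONTHS",
    "N_EXAMS",
    "ConfigError",
    "GrowthParams",
    "SimConfig",
    "sample_params",
    "eval_curves",
    "generate_cohort",
]

#: Median ages (months) of the seven scheduled check-ups, exams I-VII.
EXAM_AGES_MONTHS: tuple[int, ...] = (5, 11, 21, 33, 45, 57, 69)
N_EXAMS = 7

_MAX_REJECTION_DRAWS = 1000


class ConfigError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


@dataclass(frozen=True)
class GrowthParams:
    """Latent growth-curve parameters for one simulated child.

    Attributes
    ----------
    sex : str
        ``"male"`` or ``"female"``.
    w0 : float
        Birth weight, kg.
    b0 : float
        BMI at birth, kg/m^2.
    b_peak : float
        BMI at the infancy peak, kg/m^2.
    t_peak : float
        Age of the infancy BMI peak, months.
    b_r : float
        BMI at the nadir, kg/m^2.
    t_r : float
        Age of the BMI nadir, months.  May exceed the last exam age, in
        which case the observed minimum sits at the final exam.
    k_reb : float
        Post-nadir rebound curvature, kg/m^2 per month^2.
    a, b_h, c_h, d_h : float
        Jenss-Bayley height coefficients (cm, cm/month, cm, 1/month).
        Birth length is ``a - c_h``.
    """

    sex: str
    w0: float
    b0: float
    b_peak: float
    t_peak: float
    b_r: float
    t_r: float
    k_reb: float
    a: float
    b_h: float
    c_h: float
    d_h: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.t_peak < self.t_r:
            raise ValueError("t_peak must precede t_r")
        if not self.b_peak > self.b_r:
            raise ValueError("b_peak must exceed b_r")
        if not self.b_peak > self.b0:
            raise ValueError("b_peak must exceed b0")
        if not self.k_reb > 0:
            raise ValueError("k_reb must be positive")
        if not self.w0 > 0:
            raise ValueError("w0 must be positive")
        if not self.a - self.c_h > 0:
            raise ValueError("a - c_h (birth length) must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Hyper-parameters of the cohort simulator.

    Every distribution hyper-parameter of :class:`GrowthParams` is exposed,
    together with the exam schedule, measurement-noise SDs and the three
    corruption probabilities.  All defaults are calibrated so that the
    cohort mean BMI tracks 17.8 kg/m^2 at 5 months down to about 15.9
    kg/m^2 near 45-57 months.
    """

    n_subjects: int = 1000
    seed: int = 0
    exam_ages: tuple[float, ...] = EXAM_AGES_MONTHS

    # sex
    p_male: float = 0.5

    # birth weight, kg: truncated normal
    w0_mean: float = 3.2
    w0_sd: float = 0.45
    w0_lo: float = 0.4
    w0_hi: float = 5.5

    # birth BMI, kg/m^2
    b0_mean: float = 13.0
    b0_sd: float = 1.0

    # age of infancy BMI peak, months: uniform
    t_peak_lo: float = 6.0
    t_peak_hi: float = 10.0

    # nadir BMI, kg/m^2
    b_r_mean: float = 15.9
    b_r_sd: float = 1.3

    # peak-minus-nadir BMI gap, kg/m^2: truncated normal
    bpeak_delta_mean: float = 2.0
    bpeak_delta_sd: float = 0.6
    bpeak_delta_min: float = 0.3

    # nadir age, months: lognormal (median exp(log_t_r_mean))
    log_t_r_mean: float = math.log(48.0)
    log_t_r_sd: float = 0.35

    # rebound curvature: lognormal
    log_k_reb_mean: float = math.log(0.0015)
    log_k_reb_sd: float = 0.5

    # Jenss-Bayley height coefficients
    a_mean: float = 82.0
    a_sd: float = 3.0
    b_h_mean: float = 0.55
    b_h_sd: float = 0.05
    birth_length_mean: float = 50.0
    birth_length_sd: float = 2.0
    d_h_mean: float = 0.065
    d_h_sd: float = 0.01

    # measurement noise SDs
    noise_height_sd: float = 0.5
    noise_weight_sd: float = 0.15

    # corruption mechanisms
    p_miss: float = 0.0
    p_shrink: float = 0.0
    p_bw_out: float = 0.0

    # optional independent Bernoulli exposure flags, name -> probability
    exposures: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        ages = tuple(self.exam_ages)
        if len(ages) < 1 or any(b <= a for a, b in zip(ages, ages[1:])):
            raise ConfigError("exam_ages must be a strictly increasing sequence")
        for name in ("p_male", "p_miss", "p_shrink", "p_bw_out"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for name, p in dict(self.exposures).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"exposure {name!r} probability must lie in [0, 1]")
        for name in (
            "w0_sd", "b0_sd", "b_r_sd", "bpeak_delta_sd", "log_t_r_sd",
            "log_k_reb_sd", "a_sd", "b_h_sd", "birth_length_sd", "d_h_sd",
            "noise_height_sd", "noise_weight_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.w0_lo > self.w0_hi:
            raise ConfigError("empty birth-weight truncation interval")
        if self.t_peak_lo > self.t_peak_hi:
            raise ConfigError("empty t_peak interval")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "SimConfig":
        """Build a config from a flat key-value mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "exam_ages" in kwargs:
            kwargs["exam_ages"] = tuple(kwargs["exam_ages"])  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -math.inf, hi: float = math.inf) -> float:
    """Draw Normal(mean, sd) truncated to [lo, hi] by rejection.

    sd == 0 degenerates to the mean (which must lie inside the interval).
    """
    if sd < 0:
        raise ConfigError("negative SD")
    if lo > hi:
        raise ConfigError("empty truncation interval")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ConfigError("degenerate mean outside truncation interval")
        return float(mean)
    for _ in range(_MAX_REJECTION_DRAWS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ConfigError(
        f"truncation interval [{lo}, {hi}] too far from Normal({mean}, {sd})"
    )


def sample_params(config: SimConfig, rng: np.random.Generator) -> GrowthParams:
    """Draw one child's :class:`GrowthParams` from the configured distributions.

    A handful of joint constraints (``t_r > t_peak``, ``b_peak > b0``) are
    enforced by resampling the offending coordinate; at the default
    hyper-parameters these resamples are rare tail events.
    """
    config.validate()
    sex = "male" if rng.random() < config.p_male else "female"
    w0 = _trunc_normal(rng, config.w0_mean, config.w0_sd, config.w0_lo, config.w0_hi)
    t_peak = float(rng.uniform(config.t_peak_lo, config.t_peak_hi))
    b_r = float(rng.normal(config.b_r_mean, config.b_r_sd))
    delta = _trunc_normal(rng, config.bpeak_delta_mean, config.bpeak_delta_sd,
                          lo=config.bpeak_delta_min)
    b_peak = b_r + delta
    # b0 strictly below the peak; resample the tail rather than clip so the
    # realised distribution stays smooth
    b0 = _trunc_normal(rng, config.b0_mean, config.b0_sd, hi=b_peak - 0.1)
    for _ in range(_MAX_REJECTION_DRAWS):
        t_r = float(np.exp(rng.normal(config.log_t_r_mean, config.log_t_r_sd)))
        if t_r > t_peak + 0.5:
            break
    else:
        raise ConfigError("could not sample t_r > t_peak")
    k_reb = float(np.exp(rng.normal(config.log_k_reb_mean, config.log_k_reb_sd)))
    a = float(rng.normal(config.a_mean, config.a_sd))
    b_h = _trunc_normal(rng, config.b_h_mean, config.b_h_sd, lo=0.01)
    birth_length = _trunc_normal(rng, config.birth_length_mean,
                                 config.birth_length_sd, lo=1.0, hi=a - 1.0)
    c_h = a - birth_length
    d_h = _trunc_normal(rng, config.d_h_mean, config.d_h_sd, lo=1e-4)
    return GrowthParams(sex=sex, w0=w0, b0=b0, b_peak=b_peak, t_peak=t_peak,
                        b_r=b_r, t_r=t_r, k_reb=k_reb, a=a, b_h=b_h,
                        c_h=c_h, d_h=d_h)


def eval_curves(p: GrowthParams, t):
    """Evaluate the noise-free BMI, height and weight curves at age ``t``.

    Parameters
    ----------
    p : GrowthParams
    t : float or array-like
        Age in months, ``t >= 0``.

    Returns
    -------
    (bmi, height, weight)
        kg/m^2, cm and kg; scalars if ``t`` is scalar, else ndarrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("age must be non-negative")
    rising = p.b_peak - (p.b_peak - p.b0) * ((p.t_peak - t_arr) / p.t_peak) ** 2
    falling = p.b_r + (p.b_peak - p.b_r) * ((p.t_r - t_arr) / (p.t_r - p.t_peak)) ** 2
    rebound = p.b_r + p.k_reb * (t_arr - p.t_r) ** 2
    bmi = np.where(t_arr < p.t_peak, rising,
                   np.where(t_arr < p.t_r, falling, rebound))
    height = p.a + p.b_h * t_arr - p.c_h * np.exp(-p.d_h * t_arr)
    weight = bmi * (height / 100.0) ** 2
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(bmi), float(height), float(weight)
    return bmi, height, weight


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and return ``(subjects, exams, truth)`` tables.

    The generator uses four independent named random streams (parameters,
    noise, corruption, exposures) spawned from ``config.seed``, and draws a
    fixed number of variates per subject from each, so switching one
    mechanism on or off never shifts the draws of the others.

    Corruptions are applied after measurement noise, in this order:

    1. each exam is independently dropped with probability ``p_miss``
       (missing exams are absent as rows in the exams table);
    2. each exam's height is independently reduced by Uniform(3, 10) cm
       with probability ``p_shrink`` (creating non-increasing records);
    3. with probability ``p_bw_out`` the recorded birth weight is replaced
       by a value outside [0.5, 5.0] kg (either side with equal chance).

    The truth table logs, per child, the latent parameters, the index
    (1-based) of the exam where the noise-free BMI curve attains its
    minimum over the schedule, and one flag column per corruption.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    params_rng, noise_rng, corrupt_rng, exposure_rng = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    ages = np.asarray(config.exam_ages, dtype=float)
    n_exams = len(ages)
    exposure_names = list(config.exposures)

    subj_rows: list[dict] = []
    exam_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []

    for i in range(config.n_subjects):
        sid = f"S{i + 1:06d}"
        p = sample_params(config, params_rng)
        bmi, height, weight = eval_curves(p, ages)
        true_nadir_exam = int(np.argmin(bmi)) + 1  # earliest tie, 1-based

        height = height + noise_rng.normal(0.0, config.noise_height_sd, n_exams)
        weight = weight + noise_rng.normal(0.0, config.noise_weight_sd, n_exams)

        # corruption draws happen unconditionally for stream stability
        miss = corrupt_rng.random(n_exams) < config.p_miss
        shrink = corrupt_rng.random(n_exams) < config.p_shrink
        shrink_amount = corrupt_rng.uniform(3.0, 10.0, n_exams)
        bw_out = corrupt_rng.random() < config.p_bw_out
        bw_side_high = corrupt_rng.random() < 0.5
        bw_low_value = corrupt_rng.uniform(0.05, 0.45)
        bw_high_value = corrupt_rng.uniform(5.05, 6.5)

        height = np.where(shrink, height - shrink_amount, height)
        recorded_w0 = p.w0
        if bw_out:
            recorded_w0 = bw_high_value if bw_side_high else bw_low_value

        # full precision: rounding here can flip near-tied BMI argmins and
        # break exact truth recovery on noise-free cohorts
        row = {"subject_id": sid, "sex": p.sex, "birth_weight_kg": recorded_w0}
        for name in exposure_names:
            row[name] = int(exposure_rng.random() < config.exposures[name])
        subj_rows.append(row)

        keep = ~miss
        if keep.any():
            exam_frames.append(pd.DataFrame({
                "subject_id": sid,
                "exam_index": np.arange(1, n_exams + 1)[keep],
                "age_months": ages[keep],
                "height_cm": height[keep],
                "weight_kg": weight[keep],
            }))

        truth = {"subject_id": sid, "true_nadir_exam": true_nadir_exam,
                 "bw_outlier": int(bw_out)}
        truth.update({f: getattr(p, f) for f in
                      ("sex", "w0", "b0", "b_peak", "t_peak", "b_r", "t_r",
                       "k_reb", "a", "b_h", "c_h", "d_h")})
        for j in range(n_exams):
            truth[f"miss_{j + 1}"] = int(miss[j])
            truth[f"shrink_{j + 1}"] = int(shrink[j])
        truth_rows.append(truth)

    subjects = pd.DataFrame(subj_rows)
    if exam_frames:
        exams = pd.concat(exam_frames, ignore_index=True)
    else:
        exams = pd.DataFrame(columns=["subject_id", "exam_index", "age_months",
                                      "height_cm", "weight_kg"])
    truth_df = pd.DataFrame(truth_rows)
    return subjects, exams, truth_df
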