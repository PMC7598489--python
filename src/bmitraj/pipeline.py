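"""End-to-end driver: simulate (optional) -> QC -> AR -> subgroups -> stats.

Writes every artifact as CSV plus a JSON run report whose record counts
chain consistently from stage to stage, and whose manifest carries a
SHA-256 digest per output file so that seeded determinism can be checked
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, ar, io, qc, stats, subgroup
from .config import PipelineConfig
from .synth import generate_cohort

__all__ = ["RunReport", "run_pipeline", "chain_total", "stats_outputs"]

log = logging.getLogger("bmitraj")


def chain_total(parts) -> int:
    """Sum stage/group counts after checking they are non-negative integers.

    The conservation primitive used by the run report: a total is only ever
    reported as the checked sum of its parts.
    """
    total = 0
    for c in parts:
        if int(c) != c or c < 0:
            raise ValueError(f"count {c!r} is not a non-negative integer")
        total += int(c)
    return total


@dataclass
class RunReport:
    config: dict
    versions: dict
    counts: dict
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def check_chain(self) -> None:
        c = self.counts
        if c["n_input"] != chain_total((c["n_excluded_birth_weight"],
                                        c["n_excluded_too_few_valid"],
                                        c["n_clean"])):
            raise ValueError("QC counts do not chain")
        if c["n_clean"] != chain_total((c["n_classified"], c["n_unclassified"])):
            raise ValueError("classification counts do not chain")

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   default=str), encoding="utf-8")
        return path


def _versions() -> dict:
    return {"bmitraj": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}


def stats_outputs(classified: pd.DataFrame, subgroups: pd.DataFrame,
                  frame: pd.DataFrame, min_curve_n: int = 100,
                  ) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Build the analytic tables from the classification/subgroup frames.

    Returns a name -> frame mapping and a list of warnings for analyses
    that had to be skipped (degenerate tables, separation, undersized
    percentile curves).
    """
    out: dict[str, pd.DataFrame] = {}
    warnings: list[str] = []

    merged = subgroups.merge(classified[["subject_id", "ar_class"]],
                             on="subject_id", validate="one_to_one")

    def _assoc(table: stats.ContingencyTable, name: str) -> None:
        counts = table.to_frame(margins=True)
        out[f"{name}_counts"] = counts.reset_index()
        pct = pd.DataFrame(table.row_percent(), index=list(table.row_levels),
                           columns=list(table.col_levels))
        out[f"{name}_row_pct"] = pct.reset_index(names=table.row_name)
        try:
            chi2, df_, p = stats.chi_square(table)
            g, _, p_g = stats.likelihood_ratio_test(table)
            out[f"{name}_tests"] = pd.DataFrame(
                {"test": ["pearson_chi2", "likelihood_ratio"],
                 "statistic": [chi2, g], "df": [df_, df_], "p": [p, p_g]})
        except stats.DegenerateTableError as exc:
            warnings.append(f"{name}: association tests skipped ({exc})")

    ar_levels = [c for c in ar.AR_CLASSES
                 if c in set(merged["ar_class"].dropna())]
    for factor in ("bmi_status", "bw_class", "rwg"):
        sub = merged
        try:
            table = stats.crosstab(sub, factor, "ar_class",
                                   col_levels=ar_levels)
        except qc.InputError as exc:
            warnings.append(f"{factor}: crosstab skipped ({exc})")
            continue
        if table.n == 0:
            warnings.append(f"{factor}: no classified subjects")
            continue
        _assoc(table, f"{factor}_by_ar")

    # birth-weight-adjusted ORs for AR before 57 months by BMI status
    model = merged[merged["ar_class"].isin(ar.AR_CLASSES)
                   & merged["bmi_status"].notna()]
    if len(model) and model["bmi_status"].nunique() > 1:
        y = stats.outcome_ar_before_57(model["ar_class"])
        if 0 < y.sum() < len(y):
            results = stats.fit_logistic(
                y, model["bmi_status"],
                covariates={"birth_weight_kg": model["birth_weight_kg"]},
                reference="normal" if "normal" in set(model["bmi_status"]) else None)
            rows = [(r.exposure, r.reference, r.oratio, r.ci_low, r.ci_high,
                     r.p, ";".join(r.adjusted), r.note) for r in results]
            out["bmi_status_or"] = pd.DataFrame(
                rows, columns=["exposure", "reference", "odds_ratio",
                               "ci_low", "ci_high", "p", "adjusted", "note"])
            for r in results:
                if r.note:
                    warnings.append(f"logistic {r.exposure}: {r.note}")
        else:
            warnings.append("logistic skipped: outcome constant")

    for sex in ("male", "female"):
        try:
            curves = stats.percentile_curves(frame, sex, min_n=min_curve_n)
            out[f"percentile_curves_{sex}"] = curves.to_frame()
        except qc.InputError as exc:
            warnings.append(f"percentile curves ({sex}) skipped: {exc}")

    ttab, skipped = stats.sex_compare(frame)
    out["sex_compare"] = ttab
    for a in skipped:
        warnings.append(f"sex comparison skipped at age {a}: one sex only")
    return out, warnings


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline and return the run report.

    Identical config + seed produces byte-identical output files.
    """
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    warnings: list[str] = []

    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        log.info("simulating cohort: n=%d seed=%d", sim.n_subjects, sim.seed)
        subjects_df, exams_df, truth_df = generate_cohort(sim)
        written = io.write_cohort(out, subjects_df, exams_df, truth_df)
        paths.extend(written.values())
        subjects_path, exams_path = written["subjects"], written["exams"]
    else:
        subjects_path, exams_path = config.subjects_path, config.exams_path

    cohort, rejects = io.load_cohort(subjects_path, exams_path)
    if len(rejects):
        paths.append(io.write_frame(rejects, out / "rejected_rows.csv"))
        warnings.append(f"{len(rejects)} malformed rows routed to rejected_rows.csv")

    clean, report = qc.apply_qc(cohort, strict=config.qc_strict)
    paths.extend(io.write_clean_cohort(out, clean).values())
    qc_path = out / "qc_report.json"
    qc_path.write_text(json.dumps(report.to_dict(), indent=2), encoding="utf-8")
    paths.append(qc_path)

    classified = ar.classify_cohort(clean, tie=config.tie_rule)
    paths.append(io.write_frame(classified, out / "ar_classification.csv"))
    n_classified = int((classified["ar_class"] != ar.UNCLASSIFIED).sum())
    if n_classified:
        prev = ar.prevalence(classified)
        paths.append(io.write_frame(prev.table.reset_index(),
                                    out / "ar_prevalence.csv"))
    else:
        warnings.append("no classified subjects; prevalence table skipped")

    thresholds = (subgroup.load_threshold_table(config.bmi_reference_path)
                  if config.bmi_reference_path else None)
    subgroups = subgroup.assign_subgroups(clean, rwg_threshold=config.rwg_threshold,
                                          thresholds=thresholds)
    paths.append(io.write_frame(subgroups, out / "subgroups.csv"))

    frame = qc.cohort_frame(clean)
    tables, stat_warnings = stats_outputs(classified, subgroups, frame,
                                          min_curve_n=config.min_curve_n)
    warnings.extend(stat_warnings)
    for name, df in tables.items():
        paths.append(io.write_frame(df, out / f"{name}.csv"))

    counts = {"n_input": report.n_input,
              "n_excluded_birth_weight": report.n_excluded_birth_weight,
              "n_excluded_too_few_valid": report.n_excluded_too_few_valid,
              "n_clean": report.n_included,
              "n_classified": n_classified,
              "n_unclassified": int(len(classified)) - n_classified}
    run_report = RunReport(config=config.echo(), versions=_versions(),
                           counts=counts, warnings=warnings,
                           manifest=io.manifest(paths))
    run_report.check_chain()
    run_report.to_json(out / "run_report.json")
    return run_report
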