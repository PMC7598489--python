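"""Cohort analytics: contingency tables, association tests, odds ratios,
logistic regression, percentile curve sets and per-exam sex comparisons.

The Pearson chi-square and likelihood-ratio (G) statistics, the crude
cross-product odds ratio, and the IRLS logistic fit are implemented from
their defining formulas; the test suite cross-checks them against
scipy/statsmodels so the two routes stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .qc import InputError

__all__ = [
    "PERCENTILE_LEVELS",
    "DegenerateTableError",
    "ContingencyTable",
    "ORResult",
    "PercentileCurveSet",
    "crosstab",
    "chi_square",
    "likelihood_ratio_test",
    "crude_or",
    "fit_logistic",
    "outcome_ar_before_57",
    "percentile_curves",
    "sex_compare",
    "reconstruct_count",
]

#: Percentile levels of the published BMI curve sets.
PERCENTILE_LEVELS = (1, 3, 5, 10, 15, 25, 50, 75, 85, 90, 95, 97, 99)

Z_95 = float(sps.norm.ppf(0.975))  # 1.959964...


class DegenerateTableError(ValueError):
    """A margin (or expected count) of zero makes the test undefined."""


@dataclass
class ContingencyTable:
    """Integer cross-tabulation of two subject-level factors.

    ``counts[i, j]`` is the number of subjects at ``row_levels[i]`` x
    ``col_levels[j]``.  ``n_excluded`` records subjects dropped for a
    missing/unclassified level on either factor.
    """

    row_name: str
    col_name: str
    row_levels: tuple
    col_levels: tuple
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_levels), len(self.col_levels)):
            raise ValueError("counts shape does not match level lists")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        self.counts = c

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_percent(self) -> np.ndarray:
        """Each cell as a percentage of its row margin."""
        m = self.row_margins.astype(float)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / m

    def col_percent(self) -> np.ndarray:
        """Each cell as a percentage of its column margin."""
        m = self.col_margins.astype(float)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / m

    def to_frame(self, margins: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=pd.Index(self.row_levels, name=self.row_name),
                          columns=pd.Index(self.col_levels, name=self.col_name))
        if margins:
            df["_total"] = self.row_margins
            df.loc["_total"] = list(self.col_margins) + [self.n]
        return df

    @classmethod
    def from_counts(cls, counts, row_levels, col_levels,
                    row_name: str = "row", col_name: str = "col",
                    n_excluded: int = 0) -> "ContingencyTable":
        return cls(row_name=row_name, col_name=col_name,
                   row_levels=tuple(row_levels), col_levels=tuple(col_levels),
                   counts=np.asarray(counts, dtype=int), n_excluded=n_excluded)


_MISSING_LEVELS = frozenset({"unclassified", "missing"})


def _known(series: pd.Series) -> pd.Series:
    return series.notna() & ~series.astype(object).isin(_MISSING_LEVELS)


def crosstab(df: pd.DataFrame, row_factor: str, col_factor: str,
             row_levels: Sequence | None = None,
             col_levels: Sequence | None = None) -> ContingencyTable:
    """Cross-tabulate two columns of a subject-level frame.

    Rows where either factor is NA, ``"missing"`` or ``"unclassified"`` are
    excluded and counted in ``n_excluded``.  Level order defaults to sorted
    observed levels; pass explicit level lists to fix (or extend) it.
    """
    for f in (row_factor, col_factor):
        if f not in df.columns:
            raise InputError(f"unknown factor {f!r}")
    keep = _known(df[row_factor]) & _known(df[col_factor])
    sub = df.loc[keep]
    rl = tuple(row_levels) if row_levels is not None else tuple(sorted(sub[row_factor].unique()))
    cl = tuple(col_levels) if col_levels is not None else tuple(sorted(sub[col_factor].unique()))
    counts = np.zeros((len(rl), len(cl)), dtype=int)
    grouped = sub.groupby([row_factor, col_factor], observed=True).size()
    ri = {v: i for i, v in enumerate(rl)}
    ci = {v: j for j, v in enumerate(cl)}
    for (r, c), n in grouped.items():
        if r in ri and c in ci:
            counts[ri[r], ci[c]] = n
    return ContingencyTable(row_name=row_factor, col_name=col_factor,
                            row_levels=rl, col_levels=cl, counts=counts,
                            n_excluded=int((~keep).sum()))


def _expected(table: ContingencyTable) -> np.ndarray:
    if table.n == 0 or np.any(table.row_margins == 0) or np.any(table.col_margins == 0):
        raise DegenerateTableError("zero margin; test undefined")
    return np.outer(table.row_margins, table.col_margins) / table.n


def _table_df(table: ContingencyTable) -> int:
    r, c = table.counts.shape
    if r < 2 or c < 2:
        raise DegenerateTableError("need at least a 2x2 table")
    return (r - 1) * (c - 1)


def chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence.

    Returns ``(statistic, df, p)`` with the statistic computed as
    sum((O - E)^2 / E) over all cells and df = (R-1)(C-1).
    """
    df = _table_df(table)
    e = _expected(table)
    stat = float((((table.counts - e) ** 2) / e).sum())
    return stat, df, float(sps.chi2.sf(stat, df))


def likelihood_ratio_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Likelihood-ratio (G) test of independence.

    ``G = 2 * sum(O * ln(O / E))`` with zero-count cells contributing 0.
    """
    df = _table_df(table)
    e = _expected(table)
    o = table.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    g = float(2.0 * terms.sum())
    return g, df, float(sps.chi2.sf(g, df))


@dataclass(frozen=True)
class ORResult:
    """One odds ratio with its Wald 95% CI.

    ``note`` is non-empty when the estimate is unreliable (separation,
    non-convergence); callers must not treat such results as silent output.
    """

    exposure: object
    reference: object
    oratio: float
    ci_low: float
    ci_high: float
    p: float
    adjusted: tuple = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.oratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not self.ci_low <= self.oratio <= self.ci_high:
            raise ValueError("CI must bracket the odds ratio")


def crude_or(table, haldane: bool = False,
             exposure="exposed", reference="unexposed") -> ORResult:
    """Crude cross-product odds ratio of a 2x2 table with a Wald 95% CI.

    ``table`` is [[a, b], [c, d]] with rows = exposure level and columns =
    outcome (event, non-event): OR = (a*d) / (b*c).  Zero cells raise
    unless ``haldane`` adds the 0.5 correction to every cell.
    """
    c = np.asarray(table, dtype=float)
    if c.shape != (2, 2):
        raise InputError("crude_or needs a 2x2 table")
    if np.any(c < 0):
        raise InputError("negative cell count")
    if np.any(c == 0):
        if not haldane:
            raise DegenerateTableError(
                "zero cell; pass haldane=True for the 0.5 correction")
        c = c + 0.5
    a, b = c[0]
    cc, d = c[1]
    oratio = (a * d) / (b * cc)
    se = float(np.sqrt((1 / c).sum()))
    log_or = float(np.log(oratio))
    lo, hi = np.exp(log_or - Z_95 * se), np.exp(log_or + Z_95 * se)
    p = float(2.0 * sps.norm.sf(abs(log_or) / se))
    return ORResult(exposure=exposure, reference=reference, oratio=float(oratio),
                    ci_low=float(lo), ci_high=float(hi), p=p)


def _irls(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
          max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic MLE by iteratively reweighted least squares.

    Returns (beta, covariance, converged).
    """
    n, p = x.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        xtwx = (x * w[:, None]).T @ x
        score = x.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = x @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1.0 - mu)
    xtwx = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


_SEPARATION_BOUND = 15.0  # |log OR| above this on converged fits ~ separation


def fit_logistic(outcome, exposure, covariates=None, reference=None,
                 tol: float = 1e-8, max_iter: int = 100) -> list[ORResult]:
    """Binary logistic regression returning one ORResult per exposure level.

    Parameters
    ----------
    outcome : array-like of 0/1
    exposure : array-like (categorical); dummy-coded against ``reference``
        (default: first level in sorted order).
    covariates : mapping name -> numeric array, optional
        Adjustment covariates entered linearly.
    reference : exposure level to use as the baseline.

    Notes
    -----
    Fits by IRLS to ``tol`` (max ``max_iter`` iterations) and reports Wald
    95% CIs on the exponentiated coefficients.  Non-convergence or runaway
    coefficients are flagged in ``note`` rather than silently returned.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InputError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise InputError("outcome is constant")
    exp_arr = np.asarray(exposure, dtype=object)
    if exp_arr.shape[0] != y.shape[0]:
        raise InputError("outcome and exposure lengths differ")
    levels = sorted(set(exp_arr.tolist()))
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise InputError(f"reference level {reference!r} not observed")
    others = [lv for lv in levels if lv != reference]

    cols = [np.ones_like(y)]
    for lv in others:
        cols.append((exp_arr == lv).astype(float))
    cov_names: tuple = ()
    if covariates:
        cov_names = tuple(covariates)
        for name in cov_names:
            v = np.asarray(covariates[name], dtype=float)
            if v.shape[0] != y.shape[0]:
                raise InputError(f"covariate {name!r} length mismatch")
            if np.any(~np.isfinite(v)):
                raise InputError(f"covariate {name!r} has non-finite values")
            cols.append(v)
    x = np.column_stack(cols)

    beta, cov, converged = _irls(x, y, tol=tol, max_iter=max_iter)
    note = ""
    if not converged:
        note = "did not converge; possible separation"
    elif others and np.max(np.abs(beta[1:1 + len(others)])) > _SEPARATION_BOUND:
        note = "runaway coefficient; possible separation"

    results = []
    for k, lv in enumerate(others, start=1):
        b = beta[k]
        se = float(np.sqrt(cov[k, k]))
        with np.errstate(over="ignore"):  # separated fits give inf bounds
            lo, hi = np.exp(b - Z_95 * se), np.exp(b + Z_95 * se)
        p = float(2.0 * sps.norm.sf(abs(b) / se)) if se > 0 else float("nan")
        results.append(ORResult(exposure=lv, reference=reference,
                                oratio=float(np.exp(b)), ci_low=float(lo),
                                ci_high=float(hi), p=p, adjusted=cov_names,
                                note=note))
    return results


def outcome_ar_before_57(ar_class) -> np.ndarray:
    """Indicator of AR before 57 months: class very_early or early."""
    arr = np.asarray(ar_class, dtype=object)
    if np.any(~np.isin(arr, ("very_early", "early", "moderate_to_late"))):
        raise InputError("ar_class contains unclassified/unknown levels")
    return np.isin(arr, ("very_early", "early")).astype(int)


@dataclass
class PercentileCurveSet:
    """Empirical BMI percentile curves for one sex.

    ``table`` is indexed by percentile level with one column per exam age.
    """

    sex: str
    levels: tuple
    ages: tuple
    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        long = self.table.reset_index().melt(id_vars="level",
                                             var_name="age_months",
                                             value_name="bmi")
        long.insert(0, "sex", self.sex)
        return long

    def plot(self, ax=None):
        """Draw the curve fan on a matplotlib axis (lazy import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for lv in self.levels:
            ax.plot(list(self.ages), self.table.loc[lv], lw=0.8, color="k")
        ax.set_xlabel("age (months)")
        ax.set_ylabel("BMI (kg/m$^2$)")
        ax.set_title(f"BMI percentile curves, {self.sex}")
        return ax


def percentile_curves(frame: pd.DataFrame, sex: str,
                      levels: Sequence[float] = PERCENTILE_LEVELS,
                      min_n: int = 100) -> PercentileCurveSet:
    """Sex-specific empirical BMI percentile curves across the exam ages.

    ``frame`` is the long cohort frame from :func:`bmitraj.qc.cohort_frame`;
    only valid exams contribute.  Raises listing the undersized exam ages
    when any age has fewer than ``min_n`` observations (needed for stable
    1st/99th percentiles).
    """
    from .subgroup import empirical_percentiles

    sub = frame[(frame["sex"] == sex) & frame["valid"]]
    ages = tuple(float(a) for a in sorted(sub["age_months"].unique()))
    if not ages:
        raise InputError(f"no valid exams for sex {sex!r}")
    undersized = [a for a in ages if (sub["age_months"] == a).sum() < min_n]
    if undersized:
        raise InputError(f"fewer than {min_n} subjects at exam ages {undersized}")
    cols = {}
    for a in ages:
        vals = sub.loc[sub["age_months"] == a, "bmi"].to_numpy()
        cols[a] = empirical_percentiles(vals, levels)
    table = pd.DataFrame(cols, index=pd.Index(levels, name="level"))
    return PercentileCurveSet(sex=sex, levels=tuple(levels), ages=ages,
                              table=table)


def sex_compare(frame: pd.DataFrame, equal_var: bool = False
                ) -> tuple[pd.DataFrame, list[float]]:
    """Per-exam male-vs-female BMI t-tests (Welch by default).

    Returns the per-age result table and the list of ages skipped because
    only one sex was observed there.
    """
    rows = []
    skipped: list[float] = []
    for a in (float(x) for x in sorted(frame["age_months"].unique())):
        at = frame[(frame["age_months"] == a) & frame["valid"]]
        m = at.loc[at["sex"] == "male", "bmi"].to_numpy()
        f = at.loc[at["sex"] == "female", "bmi"].to_numpy()
        if len(m) < 2 or len(f) < 2:
            skipped.append(a)
            continue
        res = sps.ttest_ind(m, f, equal_var=equal_var)
        rows.append((a, len(m), len(f), float(m.mean()), float(f.mean()),
                     float(res.statistic), float(res.df), float(res.pvalue)))
    table = pd.DataFrame(rows, columns=["age_months", "n_male", "n_female",
                                        "mean_male", "mean_female", "t", "df", "p"])
    return table, skipped


def reconstruct_count(total: int, percent: float) -> int:
    """Nearest integer count for a printed ``percent`` of ``total`` subjects."""
    if total < 0:
        raise InputError("total must be non-negative")
    if not 0 <= percent <= 100:
        raise InputError("percent must lie in [0, 100]")
    return int(round(total * percent / 100.0))
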