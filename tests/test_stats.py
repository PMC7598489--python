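import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bmitraj.qc import InputError, cohort_frame
from bmitraj.stats import (ContingencyTable, DegenerateTableError, chi_square,
                           crosstab, crude_or, fit_logistic,
                           likelihood_ratio_test, outcome_ar_before_57,
                           percentile_curves, reconstruct_count, sex_compare)


def table_2x2(a, b, c, d):
    return ContingencyTable.from_counts([[a, b], [c, d]],
                                        ["exposed", "unexposed"],
                                        ["event", "no_event"])


class TestCrosstab:
    def test_balanced_2x3_design(self):
        df = pd.DataFrame({"r": ["a"] * 6 + ["b"] * 6,
                           "c": ["x", "y", "z"] * 4})
        t = crosstab(df, "r", "c")
        assert t.counts.tolist() == [[2, 2, 2], [2, 2, 2]]
        assert t.row_margins.tolist() == [6, 6]
        assert t.col_margins.tolist() == [4, 4, 4]
        assert t.n == 12 and t.n_excluded == 0

    def test_unclassified_rows_excluded_and_counted(self):
        df = pd.DataFrame({"r": ["a", "a", "b", None],
                           "c": ["x", "unclassified", "x", "x"]})
        t = crosstab(df, "r", "c")
        assert t.n == 2 and t.n_excluded == 2

    def test_unknown_factor(self):
        with pytest.raises(InputError):
            crosstab(pd.DataFrame({"r": []}), "r", "nope")

    def test_empty_cohort_zero_table(self):
        t = crosstab(pd.DataFrame({"r": [], "c": []}), "r", "c")
        assert t.n == 0 and t.counts.size == 0

    def test_permutation_invariance_and_conservation(self, rng):
        df = pd.DataFrame({"r": rng.choice(["a", "b", "c"], 200),
                           "c": rng.choice(["x", "y"], 200)})
        t1 = crosstab(df, "r", "c")
        t2 = crosstab(df.sample(frac=1, random_state=0), "r", "c")
        assert np.array_equal(t1.counts, t2.counts)
        assert t1.counts.sum() == 200

    def test_obesity_row_reconstruction(self):
        # printed row n and within-row shares -> cell counts
        counts = [reconstruct_count(826, p) for p in (88.7, 6.9, 4.4)]
        assert counts == [733, 57, 36]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable.from_counts([[1, -1]], ["a"], ["x", "y"])


class TestChiSquare:
    def test_perfect_independence(self):
        stat, df, p = chi_square(table_2x2(10, 10, 10, 10))
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_evaluated_2x2(self):
        # all expected counts are 15; sum of 4 * (5^2 / 15) = 20/3
        stat, df, _ = chi_square(table_2x2(20, 10, 10, 20))
        assert stat == pytest.approx(20.0 / 3.0)
        assert df == 1

    def test_bruteforce_double_loop_oracle(self, rng):
        counts = rng.integers(1, 40, size=(3, 4))
        t = ContingencyTable.from_counts(counts, list("abc"), list("wxyz"))
        stat, df, p = chi_square(t)
        n = counts.sum()
        brute = 0.0
        for i in range(3):
            for j in range(4):
                e = counts[i].sum() * counts[:, j].sum() / n
                brute += (counts[i, j] - e) ** 2 / e
        assert stat == pytest.approx(brute)

    def test_matches_scipy(self, rng):
        counts = rng.integers(1, 40, size=(2, 3))
        t = ContingencyTable.from_counts(counts, ["a", "b"], ["x", "y", "z"])
        stat, df, p = chi_square(t)
        ref = sps.chi2_contingency(counts, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square(table_2x2(0, 0, 10, 20))

    def test_one_row_degenerate(self):
        t = ContingencyTable.from_counts([[5, 5]], ["a"], ["x", "y"])
        with pytest.raises(DegenerateTableError):
            chi_square(t)


class TestLikelihoodRatio:
    def test_independent_table_zero(self):
        g, df, p = likelihood_ratio_test(table_2x2(10, 10, 10, 10))
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_2x2(self):
        # 2 * (2*20*ln(20/15) + 2*10*ln(10/15)) = 6.795961...
        g, df, _ = likelihood_ratio_test(table_2x2(20, 10, 10, 20))
        assert g == pytest.approx(6.7959615, abs=1e-6)

    def test_zero_cell_contributes_zero(self):
        g, _, _ = likelihood_ratio_test(table_2x2(0 + 5, 5, 5, 0 + 5))
        t = ContingencyTable.from_counts([[0, 10], [10, 10]],
                                         ["a", "b"], ["x", "y"])
        g0, _, _ = likelihood_ratio_test(t)
        assert np.isfinite(g0)

    def test_asymptotic_agreement_near_independence(self, rng):
        base = np.array([[400, 600], [410, 590]])
        g, _, _ = likelihood_ratio_test(
            ContingencyTable.from_counts(base, ["a", "b"], ["x", "y"]))
        chi, _, _ = chi_square(
            ContingencyTable.from_counts(base, ["a", "b"], ["x", "y"]))
        assert g == pytest.approx(chi, rel=0.01)


class TestCrudeOr:
    def test_cross_product(self):
        r = crude_or([[90, 10], [50, 50]])
        assert r.oratio == pytest.approx(9.0)

    def test_symmetric_table_or_one(self):
        r = crude_or([[25, 25], [25, 25]])
        assert r.oratio == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high
        assert r.p == pytest.approx(1.0)

    def test_zero_cell_raises_unless_haldane(self):
        with pytest.raises(DegenerateTableError):
            crude_or([[0, 10], [5, 5]])
        r = crude_or([[0, 10], [5, 5]], haldane=True)
        assert r.oratio > 0

    def test_wald_ci_matches_bootstrap(self, rng):
        # resampling oracle: bootstrap subjects, compare CI half-widths
        a, b, c, d = 120, 380, 60, 440
        rows = (["ee"] * a + ["en"] * b + ["ue"] * c + ["un"] * d)
        base = crude_or([[a, b], [c, d]])
        log_ors = []
        arr = np.array(rows)
        for _ in range(400):
            s = rng.choice(arr, size=arr.size, replace=True)
            aa, bb = np.sum(s == "ee"), np.sum(s == "en")
            cc, dd = np.sum(s == "ue"), np.sum(s == "un")
            if min(aa, bb, cc, dd) > 0:
                log_ors.append(np.log(aa * dd / (bb * cc)))
        boot_se = np.std(log_ors, ddof=1)
        wald_se = (np.log(base.ci_high) - np.log(base.oratio)) / 1.959964
        assert wald_se == pytest.approx(boot_se, rel=0.15)


class TestFitLogistic:
    def test_single_binary_exposure_equals_crude_or(self, rng):
        a, b, c, d = 90, 10, 50, 50
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[["e"] * (a + b), ["u"] * (c + d)]
        fit = fit_logistic(y, x, reference="u")[0]
        ref = crude_or([[a, b], [c, d]])
        assert fit.oratio == pytest.approx(ref.oratio, rel=1e-6)
        assert fit.ci_low == pytest.approx(ref.ci_low, rel=1e-5)
        assert fit.ci_high == pytest.approx(ref.ci_high, rel=1e-5)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 800
        x1 = rng.choice(["a", "b", "c"], n)
        cov = rng.normal(3.2, 0.5, n)
        logit = -1 + 0.8 * (x1 == "b") + 0.3 * (x1 == "c") + 0.4 * (cov - 3.2)
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        fit = fit_logistic(y.astype(int), x1, covariates={"bw": cov},
                           reference="a")
        design = np.column_stack([np.ones(n), x1 == "b", x1 == "c", cov])
        ref = sm.Logit(y.astype(float), design).fit(disp=0)
        assert fit[0].oratio == pytest.approx(np.exp(ref.params[1]), rel=1e-5)
        assert fit[1].oratio == pytest.approx(np.exp(ref.params[2]), rel=1e-5)

    def test_null_coverage_simulation(self):
        # exposure independent of outcome: CI should contain 1 ~95% of runs
        hits = 0
        reps = 30
        for seed in range(reps):
            r = np.random.default_rng(seed)
            y = (r.random(5000) < 0.3).astype(int)
            x = r.choice(["e", "u"], 5000)
            res = fit_logistic(y, x, reference="u")[0]
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert hits >= reps - 4

    def test_irrelevant_covariate_leaves_or_stable(self, rng):
        n = 4000
        x = rng.choice(["e", "u"], n)
        logit = -0.5 + 1.0 * (x == "e")
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        noise = rng.normal(0, 1, n)  # true log-OR 0
        plain = fit_logistic(y, x, reference="u")[0]
        adjusted = fit_logistic(y, x, covariates={"z": noise}, reference="u")[0]
        assert adjusted.oratio == pytest.approx(plain.oratio, rel=0.02)

    def test_constant_outcome_rejected(self):
        with pytest.raises(InputError):
            fit_logistic(np.ones(10), ["a"] * 5 + ["b"] * 5)

    def test_separation_flagged_not_silent(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[["e"] * 20, ["u"] * 20]  # perfect separation
        res = fit_logistic(y, x, reference="u")[0]
        assert res.note != ""

    def test_outcome_indicator(self):
        arr = ["very_early", "early", "moderate_to_late"]
        np.testing.assert_array_equal(outcome_ar_before_57(arr), [1, 1, 0])
        with pytest.raises(InputError):
            outcome_ar_before_57(["unclassified"])


class TestPercentileCurves:
    def test_constant_bmi_collapses_all_levels(self, clean_records):
        clean, _ = clean_records
        frame = cohort_frame(clean)
        frame = frame[frame["valid"]].copy()
        frame["bmi"] = 16.0
        curves = percentile_curves(frame, "male", min_n=10)
        assert np.allclose(curves.table.to_numpy(), 16.0)

    def test_levels_ordered_at_every_exam(self, clean_records):
        clean, _ = clean_records
        frame = cohort_frame(clean)
        curves = percentile_curves(frame, "male", min_n=50)
        assert (curves.table.diff().dropna() >= 0).all().all()

    def test_undersized_exams_listed(self, clean_records):
        clean, _ = clean_records
        frame = cohort_frame(clean)
        with pytest.raises(InputError, match=r"\[5.0"):
            percentile_curves(frame, "male", min_n=10 ** 6)

    def test_duplication_invariance(self, clean_records):
        # type-7 interpolation positions shift slightly when the sample is
        # duplicated ((n-1)p vs (2n-1)p), so invariance is approximate at
        # finite n and exact only in the large-n limit
        clean, _ = clean_records
        frame = cohort_frame(clean)
        once = percentile_curves(frame, "female", min_n=10)
        twice = percentile_curves(pd.concat([frame, frame]), "female", min_n=10)
        assert np.allclose(once.table.to_numpy(), twice.table.to_numpy(),
                           atol=0.25)
        # interior levels are already tight at n ~ a few hundred
        pd.testing.assert_frame_equal(once.table.loc[25:85],
                                      twice.table.loc[25:85], atol=0.02,
                                      check_exact=False)

    def test_median_curve_tracks_generator_median(self, pristine_cohort,
                                                  clean_records):
        from bmitraj.synth import SimConfig, GrowthParams, eval_curves

        clean, _ = clean_records
        frame = cohort_frame(clean)
        curves = percentile_curves(frame, "male", min_n=50)
        cfg = SimConfig()
        median_child = GrowthParams(
            sex="male", w0=cfg.w0_mean, b0=cfg.b0_mean,
            b_peak=cfg.b_r_mean + cfg.bpeak_delta_mean, t_peak=8.0,
            b_r=cfg.b_r_mean, t_r=48.0, k_reb=0.0015, a=cfg.a_mean,
            b_h=cfg.b_h_mean, c_h=cfg.a_mean - cfg.birth_length_mean,
            d_h=cfg.d_h_mean)
        for age in (33, 45, 57):
            bmi, _, _ = eval_curves(median_child, float(age))
            assert curves.table.loc[50, age] == pytest.approx(bmi, abs=0.6)


class TestSexCompare:
    def test_identical_distributions(self):
        rows = []
        for i, b in enumerate([17.0, 16.5, 16.0]):
            for sex in ("male", "female"):
                for j in range(3):
                    rows.append((f"{sex}{j}", sex, 5 + 12 * i, True, b + 0.1 * j))
        frame = pd.DataFrame(rows, columns=["subject_id", "sex", "age_months",
                                            "valid", "bmi"])
        table, skipped = sex_compare(frame)
        assert skipped == []
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_hand_formula_on_toy_input(self):
        m = np.array([16.0, 16.4, 16.8])
        f = np.array([15.5, 15.9, 16.9])
        frame = pd.DataFrame({
            "subject_id": list("abcdef"),
            "sex": ["male"] * 3 + ["female"] * 3,
            "age_months": 45, "valid": True, "bmi": np.r_[m, f]})
        table, _ = sex_compare(frame)
        expected_t = (m.mean() - f.mean()) / np.sqrt(
            m.var(ddof=1) / 3 + f.var(ddof=1) / 3)
        assert table.loc[0, "t"] == pytest.approx(expected_t)

    def test_one_sex_exam_skipped(self):
        frame = pd.DataFrame({
            "subject_id": ["a", "b"], "sex": ["male", "male"],
            "age_months": [5, 5], "valid": True, "bmi": [17.0, 17.5]})
        table, skipped = sex_compare(frame)
        assert skipped == [5] and len(table) == 0

    def test_power_under_mean_shift(self):
        # 0.5 kg/m^2 shift, SD 1.3, n=2000/arm: detectable in every seed
        for seed in range(20):
            r = np.random.default_rng(seed)
            frame = pd.DataFrame({
                "subject_id": [str(i) for i in range(4000)],
                "sex": ["male"] * 2000 + ["female"] * 2000,
                "age_months": 45, "valid": True,
                "bmi": np.r_[r.normal(16.4, 1.3, 2000),
                             r.normal(15.9, 1.3, 2000)]})
            table, _ = sex_compare(frame)
            assert table.loc[0, "p"] < 0.001
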