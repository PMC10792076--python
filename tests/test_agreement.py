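"""Agreement-statistics core vs the brute-force sums-of-squares oracle."""

import numpy as np
import pytest

from gaitval import agreement as ag
from gaitval.errors import DataError, UndefinedStatisticError

from oracles import (brute_force_anova, brute_force_eta2, brute_force_icc_a_k,
                     brute_force_sem)


class TestIccOracle:
    def test_matches_brute_force_on_random_matrices(self, rng):
        """ICC, eta2 and SEM agree with explicit double-loop sums of squares."""
        for _ in range(60):
            n = int(rng.integers(4, 12))
            k = int(rng.integers(2, 5))
            m = rng.normal(rng.normal(0, 3), 1.0, size=(n, k)) \
                + rng.normal(0, 2, size=(n, 1))
            res = ag.icc_two_way(m, model="ICC2k")
            assert res.icc == pytest.approx(brute_force_icc_a_k(m), abs=1e-10)
            eta2, _ = ag.rm_anova_eta2(m)
            assert eta2 == pytest.approx(brute_force_eta2(m), abs=1e-10)
            metrics = ag.sem_mdc(res.icc, res.anova_ss["ss_total"], n)
            assert metrics.sem == pytest.approx(brute_force_sem(m, res.icc),
                                                abs=1e-10)

    def test_ss_decomposition_sums_to_total(self, rng):
        m = rng.normal(size=(7, 3)) + rng.normal(0, 2, size=(7, 1))
        res = ag.icc_two_way(m)
        ss = res.anova_ss
        assert ss["ss_rows"] + ss["ss_cols"] + ss["ss_error"] == \
            pytest.approx(ss["ss_total"], abs=1e-9)

    def test_both_model_labels_share_the_estimator(self, rng):
        m = rng.normal(size=(8, 3)) + rng.normal(0, 2, size=(8, 1))
        a = ag.icc_two_way(m, model="ICC2k")
        b = ag.icc_two_way(m, model="ICC3k")
        assert a.icc == b.icc
        assert a.model != b.model

    def test_identical_columns_give_perfect_agreement(self):
        col = np.array([1.0, 2.0, 5.0, 3.0, 4.0])
        m = np.column_stack([col, col, col])
        res = ag.icc_two_way(m)
        assert res.icc == pytest.approx(1.0)
        metrics = ag.sem_mdc(res.icc, res.anova_ss["ss_total"], 5)
        assert metrics.sem == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix_is_flagged_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ag.icc_two_way(np.full((5, 3), 2.0))

    def test_ci_brackets_the_estimate(self, rng):
        m = rng.normal(size=(10, 3)) + rng.normal(0, 2, size=(10, 1))
        res = ag.icc_two_way(m)
        lo, hi = res.ci95
        assert lo <= res.icc <= hi

    def test_agrees_with_pingouin(self):
        """Independent cross-check against an established implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(5)
        m = rng.normal(size=(12, 3)) + rng.normal(0, 2, size=(12, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "value": m.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="value").set_index("Type")
        row = "ICC2k" if "ICC2k" in ref.index else "ICC(A,k)"
        res = ag.icc_two_way(m, model="ICC2k")
        assert res.icc == pytest.approx(ref.loc[row, "ICC"], abs=1e-6)
        ref_ci = np.asarray(ref.loc[row].filter(like="CI").iloc[0])
        assert res.ci95[0] == pytest.approx(ref_ci[0], abs=0.02)
        assert res.ci95[1] == pytest.approx(ref_ci[1], abs=0.02)


class TestVarianceComponentRecovery:
    def test_icc2k_converges_to_analytic_value(self, rng):
        """Simulated ratings with known variance components recover the
        analytic average-measures agreement coefficient."""
        s2_s, s2_r, s2_e, n, k = 4.0, 0.25, 1.0, 200, 3
        expected = s2_s / (s2_s + (s2_r + s2_e) / k)
        est = []
        for _ in range(300):
            m = (rng.normal(0, np.sqrt(s2_s), size=(n, 1))
                 + rng.normal(0, np.sqrt(s2_r), size=(1, k))
                 + rng.normal(0, np.sqrt(s2_e), size=(n, k)))
            est.append(ag.icc_two_way(m).icc)
        assert np.mean(est) == pytest.approx(expected, abs=0.01)


class TestReliabilityMetrics:
    def test_sem_and_mdc_closed_forms(self):
        m = ag.sem_mdc(icc=0.75, total_ss=4.0 * 9, n=10)  # sd_total = 2
        assert m.sd_total == pytest.approx(2.0)
        assert m.sem == pytest.approx(1.0)
        assert m.mdc95 == pytest.approx(1.96 * np.sqrt(2))

    def test_mdc_from_sem_of_toe_off_scale(self):
        # a SEM of 0.27 cycle-percent (zero agreement, SD 0.27) maps to ~0.75
        n = 18
        m = ag.sem_mdc(icc=0.0, total_ss=0.27 ** 2 * (n - 1), n=n)
        assert m.sem == pytest.approx(0.27)
        assert m.mdc95 == pytest.approx(0.7484, abs=1e-3)

    def test_perfect_icc_gives_zero_sem(self):
        m = ag.sem_mdc(icc=1.0, total_ss=50.0, n=10)
        assert m.sem == 0.0 and m.mdc95 == 0.0


class TestPairedAgreement:
    def test_identical_samples_collapse(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = ag.paired_agreement(a, a)
        assert res.mean_diff == 0.0
        assert res.cohens_d == 0.0
        bias, lo, hi = res.bland_altman
        assert lo == bias == hi == 0.0

    def test_constant_nonzero_difference_is_flagged(self):
        a = np.array([2.0, 3.0, 4.0])
        res = ag.paired_agreement(a, a - 1.0)
        assert np.isnan(res.cohens_d)
        assert res.flags

    def test_limits_of_agreement_cover_95_percent(self, rng):
        """Monte-Carlo: ~95% of normal differences fall inside the LoA."""
        n = 10_000
        b = rng.normal(10, 1, size=n)
        a = b + rng.normal(0.5, 0.3, size=n)
        res = ag.paired_agreement(a, b)
        _, lo, hi = res.bland_altman
        d = a - b
        frac = np.mean((d >= lo) & (d <= hi))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_cohens_d_definition(self, rng):
        a = rng.normal(1.0, 1.0, size=50)
        b = rng.normal(0.0, 1.0, size=50)
        res = ag.paired_agreement(a, b)
        d = a - b
        assert res.cohens_d == pytest.approx(d.mean() / d.std(ddof=1))


class TestRmAnova:
    def test_identical_columns_give_zero_effect(self):
        col = np.array([1.0, 4.0, 2.0, 3.0])
        eta2, p = ag.rm_anova_eta2(np.column_stack([col, col]))
        assert eta2 == pytest.approx(0.0, abs=1e-12)

    def test_large_column_shift_drives_eta2_toward_one(self, rng):
        m = rng.normal(size=(6, 3))
        m[:, 2] += 1e4
        eta2, p = ag.rm_anova_eta2(m)
        assert eta2 > 0.999
        assert p < 1e-6


class TestOutlierScreen:
    def test_hand_computed_two_sd_exclusion(self):
        vals = np.array([0.0] * 9 + [10.0])   # mean 1, sample SD sqrt(10)
        kept, excluded = ag.outlier_screen(vals)
        assert list(excluded) == [9]
        assert len(kept) == 9

    def test_equal_values_keep_everyone(self):
        kept, excluded = ag.outlier_screen(np.full(8, 3.0))
        assert excluded.size == 0

    def test_two_subjects_disable_the_screen_with_warning(self):
        with pytest.warns(UserWarning):
            kept, excluded = ag.outlier_screen(np.array([0.0, 100.0]))
        assert excluded.size == 0

    def test_any_outcome_rule_excludes_on_a_single_column(self, rng):
        m = rng.normal(size=(10, 3))
        m[4, 2] = 50.0
        kept, excluded = ag.outlier_screen(m)
        assert 4 in excluded


class TestCv:
    def test_basic_value_and_constant_case(self):
        assert ag.cv_percent([9.0, 10.0, 11.0]) == pytest.approx(
            100 * np.std([9, 10, 11], ddof=1) / 10)
        assert ag.cv_percent(np.full(5, 7.0)) == 0.0

    def test_table_scale_magnitude(self, rng):
        # SD ~0.9 on a mean ~59.3 gives a CV near 1.5%
        vals = 59.3 + 0.9 * rng.standard_normal(4000)
        assert ag.cv_percent(vals) == pytest.approx(1.52, abs=0.15)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ag.cv_percent([-1.0, 1.0, 0.0])


class TestModelLayer:
    def test_reliability_model_end_to_end(self, rng):
        m = rng.normal(size=(10, 3)) + rng.normal(0, 2, size=(10, 1))
        res = ag.ReliabilityModel(m, model="ICC2k", parameter="stride time",
                                  unit="s").fit()
        assert 0 < res.icc <= 1
        assert res.sem >= 0
        assert res.mdc95 == pytest.approx(res.sem * 1.96 * np.sqrt(2))
        assert "ICC" in res.summary()
        stats = res.condition_stats()
        assert len(stats) == 3

    def test_method_comparison_end_to_end(self, rng):
        b = rng.normal(60, 5, size=15)
        a = b + rng.normal(-1.0, 1.0, size=15)
        res = ag.MethodComparison(a, b, parameter="knee RoM", unit="deg").fit()
        assert res.mean_diff == pytest.approx(np.mean(a - b))
        assert res.icc_result is not None
        assert "Bland" in res.summary() or "agreement" in res.summary()
        data = res.bland_altman_data()
        assert len(data) == 15

    def test_classification_thresholds(self):
        assert ag.classify_icc(0.95) == "acceptable (individual decisions)"
        assert ag.classify_icc(0.8, "reliability") == "acceptable"
        assert ag.classify_icc(0.72, "validity") == "acceptable"
        assert ag.classify_icc(0.72, "reliability") == "not acceptable"

    def test_matrix_invariants_enforced(self):
        with pytest.raises(DataError):
            ag.RatingsMatrix(np.zeros((2, 3)))
        with pytest.raises(DataError):
            ag.RatingsMatrix(np.zeros((5, 1)))
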