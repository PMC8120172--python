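import itertools
import math

import numpy as np
import pytest
from scipy import stats

from colodefense.cohort import Cohort, SubjectRecord
from colodefense.calling import SampleCall, call_cohort
from colodefense.diagnostics import (
    DegenerateTableError,
    InconsistentStratumError,
    age_bin,
    combined_score,
    diagnostic_performance,
    mann_whitney,
    pearson_chi_square,
    pool_strata,
    roc_curve,
    round1,
    stratified_report,
    two_sample_t,
)
from colodefense.examples import crc_full_fixture


def bools(n_true, n_total):
    return [True] * n_true + [False] * (n_total - n_true)


class TestDiagnosticPerformance:
    def test_study_overall_counts(self):
        """78/91 positive cases and 33/38 negative controls give the
        85.7% / 86.8% operating point."""
        perf = diagnostic_performance(bools(78, 91), bools(5, 38))
        assert perf.sensitivity_pct == 85.7
        assert perf.specificity_pct == 86.8
        assert perf.true_positives == 78
        assert perf.true_negatives == 33

    def test_perfect_classifier(self):
        perf = diagnostic_performance([True] * 10, [False] * 10)
        assert perf.sensitivity_pct == 100.0
        assert perf.specificity_pct == 100.0

    def test_counts_are_conserved(self):
        perf = diagnostic_performance(bools(69, 91), bools(2, 38))
        assert perf.true_positives + (perf.n_cases - perf.true_positives) == 91
        assert 0 <= perf.true_negatives <= perf.n_controls

    def test_point_estimate_inside_ci(self):
        perf = diagnostic_performance(bools(69, 91), bools(2, 38))
        lo, hi = perf.sensitivity_ci95
        assert lo <= perf.sensitivity_pct <= hi

    def test_wilson_interval_against_closed_form(self):
        """Wilson score interval for 69/91 recomputed from its formula."""
        z = 1.959963984540054
        k, n = 69, 91
        p = k / n
        denom = 1 + z * z / n
        center = p + z * z / (2 * n)
        half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
        lo, hi = (center - half) / denom, (center + half) / denom
        perf = diagnostic_performance(bools(69, 91), bools(0, 38))
        assert perf.sensitivity_ci95 == (round1(100 * lo), round1(100 * hi))

    def test_clopper_pearson_selectable(self):
        wilson = diagnostic_performance(bools(69, 91), bools(0, 38))
        cp = diagnostic_performance(
            bools(69, 91), bools(0, 38), ci_method="clopper_pearson"
        )
        assert cp.sensitivity_ci95 != wilson.sensitivity_ci95

    def test_wilson_interval_shrinks_with_n(self):
        widths = []
        for n in (20, 40, 80, 160, 320):
            k = int(0.6 * n)
            perf = diagnostic_performance(bools(k, n), bools(0, 10))
            lo, hi = perf.sensitivity_ci95
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_performance([], [False])


class TestPoolStrata:
    def test_gender_strata_pool_to_overall_combined(self):
        assert pool_strata([(55, 81.8), (36, 91.7)]) == 85.7

    def test_gender_strata_pool_to_overall_msept9(self):
        assert pool_strata([(55, 74.6), (36, 77.8)]) == 75.8

    def test_t_stage_strata_pool_to_overall_msdc2(self):
        strata = [(4, 25.0), (1, 100.0), (13, 53.9), (49, 63.3), (9, 77.8), (15, 53.3)]
        assert pool_strata(strata) == 60.4

    def test_single_stratum_identity(self):
        assert pool_strata([(91, 100.0)]) == 100.0
        assert pool_strata([(44, 81.8)]) == 81.8

    def test_order_invariance(self):
        strata = [(55, 81.8), (36, 91.7), (13, 53.8)]
        assert pool_strata(strata) == pool_strata(strata[::-1])

    def test_slop_in_last_printed_digit_tolerated(self):
        # 41/55 = 74.5% but a printed 74.6 still reconstructs 41 positives
        assert pool_strata([(55, 74.6)]) == 74.5

    def test_impossible_percentage_rejected(self):
        with pytest.raises(InconsistentStratumError):
            pool_strata([(7, 120.0)])
        with pytest.raises(InconsistentStratumError):
            pool_strata([(7, float("nan"))])

    def test_nonpositive_stratum_rejected(self):
        with pytest.raises(ValueError):
            pool_strata([(0, 50.0)])


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_curve([20.0, 21.0, 22.0], [40.0, 41.0, 42.0])
        assert roc.auc == 1.0

    def test_identical_distributions(self):
        roc = roc_curve([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert roc.auc == pytest.approx(0.5)

    def test_curve_is_monotone_from_origin_to_one(self, rng):
        roc = roc_curve(rng.normal(30, 3, 40).tolist(), rng.normal(40, 3, 25).tolist())
        fpr = [p[0] for p in roc.points]
        tpr = [p[1] for p in roc.points]
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))

    def test_auc_equals_exhaustive_pair_counting(self, rng):
        """5 cases vs 5 controls: AUC equals P(case<control) + 0.5 P(tie)."""
        cases = rng.integers(20, 35, 5).astype(float)
        controls = rng.integers(25, 45, 5).astype(float)
        wins = sum(
            (c < k) + 0.5 * (c == k)
            for c, k in itertools.product(cases, controls)
        )
        roc = roc_curve(cases.tolist(), controls.tolist())
        assert roc.auc == pytest.approx(wins / 25)

    def test_auc_u_duality(self, rng):
        """Trapezoid AUC equals the tie-corrected Mann-Whitney U/(n_a n_b)."""
        for _ in range(20):
            a = np.round(rng.normal(30, 4, rng.integers(5, 30)), 1)
            b = np.round(rng.normal(33, 4, rng.integers(5, 30)), 1)
            u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
            roc = roc_curve(a.tolist(), b.tolist(), lower_is_disease=False)
            # mannwhitneyu returns U for a "greater", i.e. pairs a > b + ties/2
            assert roc.auc == pytest.approx(u / (len(a) * len(b)))

    def test_auc_invariant_under_monotone_transform(self, rng):
        a = rng.normal(30, 4, 25)
        b = rng.normal(35, 4, 30)
        base = roc_curve(a.tolist(), b.tolist()).auc
        assert roc_curve(np.exp(a / 10).tolist(), np.exp(b / 10).tolist()).auc == (
            pytest.approx(base)
        )
        assert roc_curve((3 * a + 7).tolist(), (3 * b + 7).tolist()).auc == (
            pytest.approx(base)
        )

    def test_constant_scores_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            roc = roc_curve([5.0] * 4, [5.0] * 6)
        assert roc.auc == 0.5
        assert roc.auc_ci95 == (0.5, 0.5)

    def test_bootstrap_ci_close_to_delong(self, rng):
        a = rng.normal(30, 3, 40).tolist()
        b = rng.normal(38, 3, 40).tolist()
        delong = roc_curve(a, b)
        boot = roc_curve(a, b, ci_method="bootstrap", n_bootstrap=500, rng=rng)
        assert boot.auc == delong.auc
        assert abs(boot.auc_ci95[0] - delong.auc_ci95[0]) < 0.05


def test_combined_score_min_semantics():
    assert combined_score(40.0, 50.0) == 40.0
    assert combined_score(50.0, 50.0) == 50.0
    assert combined_score(40.0, 30.0, method="mean") == 35.0


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(8.0)  # n_a n_b / 2
        assert res.p_value == pytest.approx(1.0, abs=0.01)

    def test_fully_separated_3v3_exact(self):
        """With complete separation the exact two-sided p is 2/20 = 0.1."""
        res = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.p_value == pytest.approx(0.1)

    def test_exact_agrees_with_normal_approximation(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.3, 1, 15)
        exact = mann_whitney(a.tolist(), b.tolist())  # 225 <= 400, no ties
        asym = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert abs(exact.p_value - float(asym.pvalue)) < 0.01

    def test_ties_fall_back_to_corrected_normal(self):
        res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert 0 <= res.p_value <= 1


class TestPearsonChiSquare:
    def test_identical_proportions_give_zero_statistic(self):
        res = pearson_chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_t_stage_positivity_against_direct_formula(self):
        """mSEPT9 positives per T stage (1/4, 0/1, 8/13, 39/49, 8/9, 13/15)
        recomputed from the chi-square definition with margin-derived
        expected counts."""
        pos = [1, 0, 8, 39, 8, 13]
        n = [4, 1, 13, 49, 9, 15]
        table = [[p, t - p] for p, t in zip(pos, n)]
        obs = np.array(table, dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat = ((obs - expected) ** 2 / expected).sum()
        res = pearson_chi_square(table)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(
            float(stats.chi2.sf(stat, (len(n) - 1) * 1))
        )

    def test_permutation_invariance(self):
        table = [[3, 9], [7, 2], [5, 5]]
        base = pearson_chi_square(table).statistic
        assert pearson_chi_square(table[::-1]).statistic == pytest.approx(base)
        flipped = [row[::-1] for row in table]
        assert pearson_chi_square(flipped).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square([[0, 5], [0, 7]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_square([[1.5, 2], [3, 4]])


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_rejects(self, rng):
        a = rng.normal(0, 1, 20)
        assert two_sample_t(a.tolist(), (a + 50).tolist()).p_value < 0.001

    def test_statistic_against_pooled_formula(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 4.0, 4.0, 5.0, 8.0]
        na, nb = len(a), len(b)
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert two_sample_t(a, b).statistic == pytest.approx(t)

    def test_zero_variance_equal_means(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0


class TestStratifiedReport:
    @staticmethod
    def _case(sid, age=60, positive=True, **kw):
        subject = SubjectRecord(
            subject_id=sid, group="CRC", sex="male", age=age, ajcc_stage="II", **kw
        )
        call = SampleCall(
            subject_id=sid,
            valid=True,
            msept9_positive=positive,
            msdc2_positive=positive,
            combined_positive=positive,
            msept9_mean_ct=40.0,
            msdc2_mean_ct=40.0,
            msept9_detected_replicates=3 if positive else 0,
            msdc2_detected_replicates=3 if positive else 0,
        )
        return subject, call

    def test_age_binning(self):
        assert age_bin(45) == "40-49"
        assert age_bin(39) == "<40"
        assert age_bin(80) == ">=80"
        subject, call = self._case("a", age=45)
        report = stratified_report(Cohort(subjects=[subject]), [call])
        row = next(
            r for r in report.rows_for("age_group") if r.stratum == "40-49"
        )
        assert row.n == 1

    def test_all_positive_gives_unit_sensitivity_and_null_tests(self):
        pairs = [self._case(f"s{i}", age=30 + 5 * i) for i in range(8)]
        cohort = Cohort(subjects=[p[0] for p in pairs])
        report = stratified_report(cohort, [p[1] for p in pairs])
        for row in report.rows:
            if row.n:
                assert row.sensitivity_pct("combined") == 100.0
        for by_marker in report.tests.values():
            for t in by_marker.values():
                if t is not None:
                    assert t.p_value == 1.0

    def test_strata_sum_to_case_total(self, rng):
        cohort = crc_full_fixture(rng)
        calls, _ = call_cohort(cohort)
        report = stratified_report(cohort, calls)
        for name in ("gender", "age_group", "t_stage"):
            assert sum(r.n for r in report.rows_for(name)) == 91

    def test_pooled_strata_match_overall_sensitivity(self, rng):
        """Pooling any stratifier's rows with pool_strata reproduces the
        overall per-marker sensitivity."""
        cohort = crc_full_fixture(rng)
        calls, _ = call_cohort(cohort)
        report = stratified_report(cohort, calls)
        overall = {
            "mSEPT9": round1(100 * 69 / 91),
            "mSDC2": round1(100 * 55 / 91),
            "combined": round1(100 * 78 / 91),
        }
        for name in ("gender", "age_group", "tumor_site"):
            rows = [r for r in report.rows_for(name) if r.n > 0]
            for marker, expected in overall.items():
                pooled = pool_strata(
                    [(r.n, r.sensitivity_pct(marker)) for r in rows]
                )
                assert pooled == expected

    def test_invalid_calls_excluded(self):
        subject, _ = self._case("a")
        invalid = SampleCall(subject_id="a", valid=False)
        report = stratified_report(Cohort(subjects=[subject]), [invalid])
        assert all(r.n == 0 for r in report.rows)


def test_round1_half_away_from_zero():
    assert round1(0.25) == 0.3
    assert round1(-0.25) == -0.3
    assert round1(81.8181) == 81.8
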