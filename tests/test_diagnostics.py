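"""Diagnostic accuracy: exact CIs, metrics, group tests, cohort summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats

from hhmismatch import (CohortRecord, ConfusionTable, accuracy_metrics,
                        clopper_pearson, cohort_summary, compare_continuous,
                        compare_proportions, confusion_from_cohort,
                        records_to_frame, round_half_up)


def make_records(n_pos, n_pos_called, n_neg, n_neg_called, field="hhm_positive"):
    """Cohort with given truth/call counts for one classifier."""
    records = []
    i = 0
    for eligible, total, called in ((True, n_pos, n_pos_called),
                                    (False, n_neg, n_neg_called)):
        for j in range(total):
            r = CohortRecord(patient_id=f"R{i:04d}", onset_to_ct_h=1.0,
                             eligible=eligible)
            setattr(r, field, j < called)
            records.append(r)
            i += 1
    return records


class TestConfusionFromCohort:
    def test_reference_cohort_hhm_counts(self):
        records = make_records(219, 195, 28, 8)
        t = confusion_from_cohort(records, "hhm_positive")
        assert (t.tp, t.fp, t.fn, t.tn) == (195, 8, 24, 20)

    def test_reference_cohort_extend_counts(self):
        records = make_records(219, 110, 28, 0, field="extend_positive")
        t = confusion_from_cohort(records, "extend_positive")
        assert (t.tp, t.fp, t.fn, t.tn) == (110, 0, 109, 28)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            confusion_from_cohort([], "hhm_positive")

    def test_missing_calls_reported_with_ids(self):
        records = make_records(2, 1, 1, 0)
        records[1].hhm_positive = None
        with pytest.raises(ValueError, match="R0001"):
            confusion_from_cohort(records, "hhm_positive")

    def test_dataframe_input_equivalent(self):
        records = make_records(10, 7, 5, 2)
        df = records_to_frame(records)
        assert confusion_from_cohort(df, "hhm_positive") == \
            confusion_from_cohort(records, "hhm_positive")

    def test_matches_brute_force_recount_on_random_cohorts(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 60))
            eligible = rng.random(n) < 0.6
            called = rng.random(n) < 0.5
            records = [
                CohortRecord(patient_id=f"X{i}", onset_to_ct_h=1.0,
                             eligible=bool(e), hhm_positive=bool(c))
                for i, (e, c) in enumerate(zip(eligible, called))
            ]
            t = confusion_from_cohort(records, "hhm_positive")
            assert t.tp == int(np.sum(eligible & called))
            assert t.fp == int(np.sum(~eligible & called))
            assert t.fn == int(np.sum(eligible & ~called))
            assert t.tn == int(np.sum(~eligible & ~called))
            assert t.total == n


def grid_search_cp(k, n, alpha=0.05, step=1e-4):
    """Brute-force Clopper-Pearson bounds on a probability grid."""
    grid = np.arange(0.0, 1.0 + step, step)
    if k == 0:
        low = 0.0
    else:
        # smallest p whose upper tail P(X >= k) exceeds alpha/2
        tail = stats.binom.sf(k - 1, n, grid)
        low = grid[np.argmax(tail > alpha / 2)]
    if k == n:
        high = 1.0
    else:
        tail = stats.binom.cdf(k, n, grid)
        high = grid[len(grid) - 1 - np.argmax(tail[::-1] > alpha / 2)]
    return float(low), float(high)


class TestClopperPearson:
    def test_printed_sensitivity_interval(self):
        low, high = clopper_pearson(195, 219)
        assert round(low, 3) == 0.841
        assert round(high, 3) == 0.929

    def test_boundaries(self):
        assert clopper_pearson(0, 28)[0] == 0.0
        assert clopper_pearson(28, 28)[1] == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)

    def test_contains_point_estimate(self):
        low, high = clopper_pearson(20, 28)
        assert low <= 20 / 28 <= high

    def test_matches_tail_inversion_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 300))
            k = int(rng.integers(0, n + 1))
            low, high = clopper_pearson(k, n)
            o_low, o_high = grid_search_cp(k, n)
            assert abs(low - o_low) <= 2e-4, (k, n)
            assert abs(high - o_high) <= 2e-4, (k, n)

    def test_coverage_at_least_nominal(self, rng):
        # exact intervals are conservative: empirical coverage of 2000
        # seeded binomial draws at n=28, p=0.7 must reach 95%
        n, p = 28, 0.7
        intervals = [clopper_pearson(k, n) for k in range(n + 1)]
        draws = rng.binomial(n, p, size=2000)
        covered = sum(intervals[k][0] <= p <= intervals[k][1] for k in draws)
        assert covered / 2000 >= 0.95


class TestAccuracyMetrics:
    def test_hhm_reference_row(self):
        acc = accuracy_metrics(ConfusionTable(tp=195, fp=8, fn=24, tn=20))
        assert acc.sensitivity.rounded()[0] == 89.0
        assert acc.specificity.rounded()[0] == 71.4
        assert acc.ppv.rounded()[0] == 96.1
        assert acc.npv.rounded()[0] == 45.5
        assert acc.auc.rounded()[0] == 80.2
        assert acc.sensitivity.rounded()[1:] == (84.1, 92.9)
        assert acc.npv.rounded()[1:] == (30.4, 61.2)

    def test_extend_reference_row(self):
        acc = accuracy_metrics(ConfusionTable(tp=110, fp=0, fn=109, tn=28))
        assert acc.sensitivity.rounded()[0] == 50.2
        assert acc.specificity.rounded()[0] == 100.0
        assert acc.ppv.rounded()[0] == 100.0
        assert acc.npv.rounded()[0] == 20.4
        assert acc.auc.rounded()[0] == 75.1

    def test_perfect_classifier(self):
        acc = accuracy_metrics(ConfusionTable(tp=10, fp=0, fn=0, tn=5))
        for name in ("sensitivity", "specificity", "ppv", "npv", "auc"):
            assert acc.metric(name).value_pct == 100.0

    def test_zero_denominator_reported_undefined(self):
        acc = accuracy_metrics(ConfusionTable(tp=0, fp=0, fn=0, tn=10))
        assert acc.sensitivity is None and acc.ppv is None
        assert acc.specificity.value_pct == 100.0
        assert acc.auc is None

    def test_point_estimates_inside_cis(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 40, size=4))
            if tp + fp + fn + tn == 0:
                continue
            acc = accuracy_metrics(ConfusionTable(tp, fp, fn, tn))
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                est = acc.metric(name)
                if est is not None:
                    assert est.ci_low_pct <= est.value_pct <= est.ci_high_pct

    def test_auc_identity_holds_exactly(self, rng):
        for _ in range(30):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 50, size=4))
            if (tp + fn) == 0 or (tn + fp) == 0:
                continue
            acc = accuracy_metrics(ConfusionTable(tp, fp, fn, tn))
            assert acc.auc.value_pct == pytest.approx(
                (acc.sensitivity.value_pct + acc.specificity.value_pct) / 2)

    def test_class_swap_exchanges_metrics(self):
        t = ConfusionTable(tp=30, fp=4, fn=6, tn=12)
        a, b = accuracy_metrics(t), accuracy_metrics(t.swapped())
        assert a.sensitivity.value_pct == b.specificity.value_pct
        assert a.specificity.value_pct == b.sensitivity.value_pct
        assert a.ppv.value_pct == b.npv.value_pct
        assert a.npv.value_pct == b.ppv.value_pct

    def test_false_omission_rate_complements_npv(self):
        acc = accuracy_metrics(ConfusionTable(tp=195, fp=8, fn=24, tn=20))
        assert acc.false_omission_rate == pytest.approx(
            100.0 - acc.npv.value_pct)

    def test_summary_shape(self):
        acc = accuracy_metrics(ConfusionTable(tp=10, fp=2, fn=3, tn=5))
        table = acc.summary()
        assert list(table.index) == ["sensitivity", "specificity",
                                     "ppv", "npv", "auc"]


class TestRounding:
    @pytest.mark.parametrize("x, expected", [
        (89.041, 89.0), (96.059, 96.1), (80.235, 80.2),
        (0.05, 0.1), (0.15, 0.2), (0.25, 0.3),  # ties go up, never banker's
        (-0.15, -0.2),
    ])
    def test_half_up(self, x, expected):
        assert round_half_up(x, 1) == expected


class TestCompareProportions:
    def test_reference_hhm_stratum_comparison(self):
        assert compare_proportions(190, 197, 5, 22) < 0.001

    def test_reference_hypertension_comparison(self):
        assert compare_proportions(154, 198, 12, 26) < 0.001

    def test_identical_proportions(self):
        assert compare_proportions(10, 20, 10, 20) == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(0, 5, 0, 8)

    def test_fisher_available(self):
        p = compare_proportions(9, 10, 1, 10, method="fisher")
        assert p == pytest.approx(stats.fisher_exact([[9, 1], [1, 9]])[1])

    def test_matches_scipy_pearson_chi2(self):
        p = compare_proportions(30, 50, 10, 40)
        expected = stats.chi2_contingency([[30, 20], [10, 30]],
                                          correction=False)[1]
        assert p == pytest.approx(expected)


class TestCompareContinuous:
    def test_identical_samples_mann_whitney(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert compare_continuous(x, x) == pytest.approx(1.0)

    def test_onset_time_groups_separate(self, rng):
        # onset-to-CT times under the generator's conditions: group normals
        # truncated at zero (resampling), eligible vs non-eligible parameters
        def truncated(mean, sd, size):
            out = np.empty(size)
            filled = 0
            while filled < size:
                draw = rng.normal(mean, sd, size=size)
                keep = draw[draw > 0][: size - filled]
                out[filled:filled + len(keep)] = keep
                filled += len(keep)
            return out

        hits = 0
        for _ in range(200):
            g1 = truncated(2.70, 2.30, 200)
            g2 = truncated(8.27, 6.10, 28)
            hits += compare_continuous(g1, g2) < 0.001
        assert hits / 200 >= 0.99

    def test_three_element_u_statistic_enumeration(self):
        x, y = [1.0, 8.0, 9.0], [2.0, 3.0, 7.0]
        observed = sum(xv > yv for xv in x for yv in y)  # U = 6 by hand
        assert observed == 6
        # exact two-sided p by enumerating all 20 rank assignments; the null
        # distribution of U is symmetric about n1*n2/2 = 4.5
        pooled = sorted(x + y)
        us = []
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            us.append(sum(a > b for a in xs for b in ys))
        p_exact = sum(abs(u - 4.5) >= abs(observed - 4.5) for u in us) / len(us)
        assert p_exact == pytest.approx(0.7)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
        assert p_scipy == pytest.approx(p_exact)

    def test_zero_variance_t_test_rejected(self):
        with pytest.raises(ValueError):
            compare_continuous([1.0, 1.0], [2.0, 2.0], method="t_test")

    def test_t_test_available(self, rng):
        g1, g2 = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        p = compare_continuous(g1, g2, method="t_test")
        assert p == pytest.approx(stats.ttest_ind(g1, g2).pvalue)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_continuous([1.0], [2.0, 3.0])


class TestCohortSummary:
    def test_binary_percentage_formatting(self):
        records = []
        for i in range(198):
            records.append(CohortRecord(patient_id=f"A{i}", onset_to_ct_h=1.0,
                                        eligible=True,
                                        covariates={"hypertension": i < 154}))
        for i in range(26):
            records.append(CohortRecord(patient_id=f"B{i}", onset_to_ct_h=6.0,
                                        eligible=False,
                                        covariates={"hypertension": i < 12}))
        table = cohort_summary(records)
        row = table.loc["hypertension"]
        assert row["pct_eligible"] == 77.8
        assert row["count_eligible"] == 154
        assert row["p_value"] < 0.001

    def test_single_record_group_sd_missing(self):
        records = [
            CohortRecord(patient_id="A", onset_to_ct_h=1.0, eligible=True,
                         covariates={"age_y": 70.0}),
            CohortRecord(patient_id="B", onset_to_ct_h=2.0, eligible=True,
                         covariates={"age_y": 80.0}),
            CohortRecord(patient_id="C", onset_to_ct_h=6.0, eligible=False,
                         covariates={"age_y": 75.0}),
        ]
        table = cohort_summary(records)
        assert np.isnan(table.loc["age_y", "sd_noneligible"])
        assert table.loc["age_y", "sd_eligible"] == pytest.approx(
            np.std([70, 80], ddof=1))

    def test_missing_values_counted(self):
        records = [
            CohortRecord(patient_id=f"{g}{i}", onset_to_ct_h=1.0,
                         eligible=g == "A",
                         covariates={"nihss": None if i == 0 else float(i)})
            for g in "AB" for i in range(4)
        ]
        table = cohort_summary(records)
        assert table.loc["nihss", "missing_eligible"] == 1
        assert table.loc["nihss", "missing_noneligible"] == 1

    def test_synthetic_cohort_group_sizes(self):
        from hhmismatch.phantom import CohortSpec, cohort_records

        records = cohort_records(CohortSpec(5, 2, 3, seed=3))
        for r in records:
            r.eligible = r.stratum != "late_no_mismatch"
        table = cohort_summary(records)
        assert table.loc["onset_to_ct_h", "n_eligible"] == 7
        assert table.loc["onset_to_ct_h", "n_noneligible"] == 3
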