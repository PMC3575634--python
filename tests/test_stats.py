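"""Cohort statistics: incidence arithmetic, tests, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from femfit.errors import InsufficientDataError
from femfit.metrics import FitnessReport
from femfit.stats import (CohortSummary, CohortTable, build_summary,
                          compare_incidence, compare_paired, incidence,
                          round_half_up, summarize_metric)


def chi2_oracle(a, b, n):
    """From-scratch Σ(O−E)²/E on the 2×2 incidence table."""
    obs = np.array([[a, n - a], [b, n - b]], float)
    E = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
    return float(((obs - E) ** 2 / E).sum())


def cohort_with_counts(n, flags_by_nail):
    """Cohort table with hand-set impingement flags per nail/region."""
    reports = []
    for i in range(n):
        for nail, regions in flags_by_nail.items():
            r = FitnessReport(femur_id=f"s{i:03d}", nail_id=nail)
            for region, count in regions.items():
                r.impinged[region] = i < count
            reports.append(r)
    return CohortTable.from_reports(reports)


class TestIncidence:
    @pytest.mark.parametrize("count, expected", [
        (29, 24.2), (7, 5.8), (9, 7.5), (64, 53.3), (52, 43.3),
        (38, 31.7), (63, 52.5), (0, 0.0),
    ])
    def test_percent_of_120(self, count, expected):
        table = cohort_with_counts(
            120, {"A": {"proximal": count}, "B": {"proximal": 0}})
        c, pct = incidence(table, "proximal", "A")
        assert c == count
        assert pct == expected

    def test_unknown_keys_raise(self):
        table = cohort_with_counts(4, {"A": {}, "B": {}})
        with pytest.raises(KeyError):
            incidence(table, "shaft", "A")
        with pytest.raises(KeyError):
            incidence(table, "proximal", "C")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(1, 500), st.integers(0, 500))
    def test_percent_identity(self, n, count):
        count = min(count, n)
        table = cohort_with_counts(n, {"A": {"middle": count}})
        _, pct = incidence(table, "middle", "A")
        assert pct == round_half_up(100.0 * count / n, 1)


class TestCompareIncidence:
    def test_frozen_chi_square_example(self):
        # oracle value computed by hand before implementation: 15.8170
        name, stat, p = compare_incidence(29, 7, 120)
        assert name == "chi_square"
        assert stat == pytest.approx(15.8170, abs=5e-4)
        assert stat == pytest.approx(chi2_oracle(29, 7, 120), abs=1e-10)

    def test_identical_counts_are_null(self):
        name, stat, p = compare_incidence(30, 30, 120)
        assert stat == 0.0
        assert p == 1.0

    def test_small_expected_counts_use_fisher(self):
        name, stat, p = compare_incidence(2, 0, 5)
        assert name == "fisher_exact"

    def test_chi_square_agrees_with_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            n = int(rng.integers(20, 300))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n + 1))
            name, stat, p = compare_incidence(a, b, n)
            if name != "chi_square":
                continue
            assert stat == pytest.approx(chi2_oracle(a, b, n), abs=1e-10)
            checked += 1

    def test_swapping_arms_leaves_p_and_chi2_unchanged(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            a, b = int(rng.integers(0, n)), int(rng.integers(0, n))
            na, sa, pa = compare_incidence(a, b, n)
            nb, sb, pb = compare_incidence(b, a, n)
            assert na == nb
            assert pa == pytest.approx(pb, rel=1e-12)
            if na == "chi_square":
                assert sa == pytest.approx(sb, rel=1e-12)


class TestSummarizeMetric:
    def test_hand_arithmetic(self):
        mean, sd, n = summarize_metric([2.0, 4.0])
        assert (round(mean, 2), round(sd, 2), n) == (3.0, 1.41, 2)

    def test_single_value_has_null_sd(self):
        assert summarize_metric([3.3]) == (3.3, None, 1)

    def test_all_null_gives_empty_summary(self):
        assert summarize_metric([None, None]) == (None, None, 0)

    def test_sampling_mean_within_3_se(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(10.0, 2.0, size=1000)
        mean, sd, n = summarize_metric(list(vals))
        assert abs(mean - 10.0) < 3 * 2.0 / np.sqrt(1000)


class TestComparePaired:
    def test_identical_lists_null(self):
        assert compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (
            "paired_t", 0.0, 1.0, 3)

    def test_constant_shift_degenerates_to_infinite_t(self):
        name, stat, p, n = compare_paired([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(stat) and stat > 0
        assert p == 0.0

    def test_nulls_drop_the_pair(self):
        name, stat, p, n = compare_paired([1.0, None, 2.0, 5.0],
                                          [1.5, 3.0, 2.5, 4.0])
        assert n == 3

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            compare_paired([1.0, None], [2.0, 3.0])

    def test_wilcoxon_alternative(self):
        rng = np.random.default_rng(4)
        a = list(rng.normal(5, 1, 20))
        b = list(rng.normal(5, 1, 20))
        name, stat, p, n = compare_paired(a, b, method="wilcoxon")
        assert name == "wilcoxon"
        assert 0.0 <= p <= 1.0


class TestBuildSummary:
    def test_counts_match_hand_tally(self):
        reports = []
        prox_flags = {"N1": [True, True, False, False],
                      "N2": [True, False, False, False]}
        for i in range(4):
            for nail in ("N1", "N2"):
                r = FitnessReport(femur_id=f"s{i}", nail_id=nail)
                r.impinged["proximal"] = prox_flags[nail][i]
                if r.impinged["proximal"]:
                    r.A_max_thickness_proximal = 2.0 + i
                r.G_max_gap_middle = 5.0 + i + (0.5 if nail == "N1" else 0.0)
                reports.append(r)
        summary = build_summary(CohortTable.from_reports(reports))
        prox = summary.incidence_rows[0]
        assert prox["count_N1"] == 2 and prox["count_N2"] == 1
        assert prox["percent_N1"] == 50.0 and prox["percent_N2"] == 25.0
        g = next(r for r in summary.metric_rows
                 if r["metric"] == "G_max_gap_middle")
        assert g["mean_N1"] == pytest.approx(7.0)
        assert g["n_pairs"] == 4

    def test_empty_cohort_rows_are_null_with_reason(self):
        reports = []
        for i in range(3):
            for nail in ("N1", "N2"):
                reports.append(FitnessReport(femur_id=f"s{i}", nail_id=nail))
        summary = build_summary(CohortTable.from_reports(reports))
        for row in summary.incidence_rows:
            assert row["percent_N1"] == 0.0
            assert row["test"] is None and "note" in row
        a_row = next(r for r in summary.metric_rows
                     if r["metric"] == "A_max_thickness_proximal")
        assert a_row["mean_N1"] is None

    def test_summary_json_roundtrip(self):
        table = cohort_with_counts(6, {"N1": {"proximal": 2, "middle": 5},
                                       "N2": {"proximal": 1}})
        summary = build_summary(table)
        back = CohortSummary.from_json(summary.to_json())
        assert back.to_dict() == summary.to_dict()

    def test_unconverged_specimens_excluded_from_metrics(self):
        reports = []
        for i in range(4):
            for nail in ("N1", "N2"):
                r = FitnessReport(femur_id=f"s{i}", nail_id=nail)
                r.G_max_gap_middle = 3.0 + i
                if i == 0 and nail == "N1":
                    r.converged = False
                reports.append(r)
        summary = build_summary(CohortTable.from_reports(reports))
        assert summary.n_unconverged == {"N1": 1, "N2": 0}
        g = next(r for r in summary.metric_rows
                 if r["metric"] == "G_max_gap_middle")
        assert g["n_N1"] == 3 and g["n_N2"] == 3
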