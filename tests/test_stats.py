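"""Validation statistics against independent oracles and identities."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

from riskval.adjudication import CTRCDCall
from riskval.models import RiskAssignment
from riskval.stats import (
    ContingencySummary,
    association_test,
    auc_with_ci,
    calibration_points,
    fisher_exact_2xk,
    incidence_table,
    one_way_anova,
    relative_risk,
)


def summary_from_counts(categories, totals, events):
    return ContingencySummary(list(categories), list(totals), list(events))


def assignments_and_calls(categories, totals, events, predicted=None):
    """Materialize per-patient assignments and adjudication calls that
    cross-tabulate back to the given counts."""
    assignments, calls = [], []
    i = 0
    for cat, n, e in zip(categories, totals, events):
        for j in range(n):
            pid = f"p{i}"
            assignments.append(RiskAssignment(
                pid, "m", raw_score=None, category=cat,
                predicted_risk=None if predicted is None else predicted[cat]))
            calls.append(CTRCDCall(
                pid, "CREC", event=j < e,
                first_event_time=90.0 if j < e else None,
                criterion="asymptomatic_drop" if j < e else "none"))
            i += 1
    return assignments, calls


class TestIncidenceTable:
    def test_reported_category_proportions(self):
        # the four-category incidence pattern of the level-combination
        # proforma in the reference cohort
        cats = ["low", "medium", "high", "very_high"]
        assignments, calls = assignments_and_calls(
            cats, [193, 404, 27, 5], [30, 109, 10, 2])
        table = incidence_table(assignments, calls, categories=cats)
        assert table.n_total == [193, 404, 27, 5]
        # 109/404 = 26.98%, which standard rounding displays as 27.0; the
        # reference table prints 26.9 (a truncation), within one display unit
        assert table.proportions_pct == [15.5, 27.0, 37.0, 40.0]
        for shown, reference in zip(table.proportions_pct, [15.5, 26.9, 37.0, 40.0]):
            assert abs(shown - reference) <= 0.1 + 1e-9

    def test_single_category_equals_overall_incidence(self):
        assignments, calls = assignments_and_calls(["all"], [50], [12])
        table = incidence_table(assignments, calls)
        assert table.proportions == [12 / 50]

    def test_zero_events_everywhere(self):
        assignments, calls = assignments_and_calls(["a", "b"], [5, 6], [0, 0])
        assert incidence_table(assignments, calls).proportions_pct == [0.0, 0.0]

    def test_patient_without_call_is_an_error(self):
        assignments, calls = assignments_and_calls(["a"], [3], [1])
        with pytest.raises(ValueError, match="without adjudication"):
            incidence_table(assignments, calls[:-1])


class TestAssociation:
    def test_identical_proportions_give_null_statistic(self):
        table = summary_from_counts(["a", "b"], [100, 50], [20, 10])
        res = association_test(table, "chi_square")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_pearson_matches_direct_observed_expected_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            k = int(rng.integers(2, 5))
            totals = rng.integers(10, 200, k)
            events = [int(rng.integers(1, t)) for t in totals]
            table = summary_from_counts([f"c{i}" for i in range(k)], totals, events)
            res = association_test(table, "chi_square")
            obs = np.array([events, totals - np.array(events)], dtype=float)
            expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
            stat = ((obs - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(stat, abs=1e-8)
            assert res.p_value == pytest.approx(
                sps.chi2.sf(stat, k - 1), abs=1e-10)

    def test_fisher_2x2_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(29)
        for _ in range(15):
            n1, n2 = rng.integers(5, 40, 2)
            e1, e2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            p_mine = fisher_exact_2xk([e1, e2], [n1, n2])
            # oracle: enumerate the hypergeometric support directly
            row1 = e1 + e2
            support = range(max(0, row1 - n2), min(n1, row1) + 1)
            probs = {a: sps.hypergeom.pmf(a, n1 + n2, n1, row1) for a in support}
            p_oracle = sum(p for a, p in probs.items()
                           if p <= probs[e1] * (1 + 1e-9))
            assert p_mine == pytest.approx(min(p_oracle, 1.0), abs=1e-9)

    def test_auto_runs_fisher_on_sparse_tables(self):
        sparse = summary_from_counts(["a", "b"], [8, 7], [1, 5])
        assert association_test(sparse, "auto").method == "fisher"
        dense = summary_from_counts(["a", "b"], [200, 200], [60, 80])
        assert association_test(dense, "auto").method == "chi_square"

    def test_chi_square_and_fisher_converge_on_well_filled_2x2(self):
        # asymptotic sanity: the exact and the uncorrected Pearson p agree
        # within 0.02 once cells are in the thousands, and the worst-case
        # discrepancy shrinks as tables grow
        rng = np.random.default_rng(41)

        def max_gap(lo, hi, reps):
            worst = 0.0
            for _ in range(reps):
                n1, n2 = (int(v) for v in rng.integers(lo, hi, 2))
                p = rng.uniform(0.25, 0.75)
                e1, e2 = int(rng.binomial(n1, p)), int(rng.binomial(n2, p))
                table = summary_from_counts(["a", "b"], [n1, n2], [e1, e2])
                worst = max(worst, abs(
                    association_test(table, "chi_square").p_value
                    - association_test(table, "fisher").p_value))
            return worst

        small, large = max_gap(120, 250, 8), max_gap(2000, 3000, 8)
        assert large < 0.02
        assert large < small

    def test_empty_category_is_an_error(self):
        table = summary_from_counts(["a", "b"], [10, 0], [2, 0])
        with pytest.raises(ValueError, match="n_total == 0"):
            association_test(table)


class TestAuc:
    def test_constant_scores_are_chance(self):
        res = auc_with_ci([1.0] * 10, [True] * 4 + [False] * 6)
        assert res.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        res = auc_with_ci([3, 4, 5, 0, 1, 2], [True] * 3 + [False] * 3)
        assert res.auc == 1.0 and res.ci_high == 1.0

    def test_small_mixed_example(self):
        # cases {3, 2}, controls {1, 3}: of 4 case-control pairs, 2 are
        # concordant and 1 tied -> (2 + 0.5) / 4
        res = auc_with_ci([3, 2, 1, 3], [True, True, False, False])
        assert res.auc == pytest.approx(0.625)

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        outcomes = rng.random(60) < 0.4
        if outcomes.all() or not outcomes.any():
            outcomes[0] = ~outcomes[0]
        a1 = auc_with_ci(scores, outcomes).auc
        a2 = auc_with_ci(np.exp(2 * scores) + 7, outcomes).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_delong_and_bootstrap_intervals_agree_roughly(self):
        rng = np.random.default_rng(17)
        scores = np.concatenate([rng.normal(1, 1, 80), rng.normal(0, 1, 120)])
        outcomes = np.array([True] * 80 + [False] * 120)
        d = auc_with_ci(scores, outcomes, method="delong")
        b = auc_with_ci(scores, outcomes, method="bootstrap", seed=5)
        assert d.auc == pytest.approx(b.auc)
        assert d.ci_low == pytest.approx(b.ci_low, abs=0.03)
        assert d.ci_high == pytest.approx(b.ci_high, abs=0.03)

    def test_all_identical_outcomes_is_an_error(self):
        with pytest.raises(ValueError, match="case"):
            auc_with_ci([1, 2, 3], [True, True, True])


class TestCalibration:
    def test_observed_risk_is_exact_event_proportion(self):
        assignments, calls = assignments_and_calls(
            ["medium"], [404], [109], predicted={"medium": 0.055})
        (pt,) = calibration_points(assignments, calls)
        assert pt.observed_risk == pytest.approx(109 / 404)
        assert pt.predicted_risk == pytest.approx(0.055)
        assert pt.ci_low < pt.observed_risk < pt.ci_high
        assert not pt.degenerate

    def test_zero_event_category_uses_flagged_fallback(self):
        assignments, calls = assignments_and_calls(
            ["low"], [40], [0], predicted={"low": 0.01})
        (pt,) = calibration_points(assignments, calls)
        assert pt.degenerate and pt.observed_risk == 0.0
        assert pt.ci_low == 0.0 and pt.ci_high > 0.0

    def test_wald_interval_matches_parametric_bootstrap(self):
        # parametric-bootstrap oracle at the fitted proportion
        rng = np.random.default_rng(7)
        for e, n in [(30, 193), (109, 404), (10, 27)]:
            assignments, calls = assignments_and_calls(
                ["c"], [n], [e], predicted={"c": 0.1})
            (pt,) = calibration_points(assignments, calls)
            draws = rng.binomial(n, e / n, size=10000) / n
            lo, hi = np.quantile(draws, [0.025, 0.975])
            assert pt.ci_low == pytest.approx(lo, abs=0.03)
            assert pt.ci_high == pytest.approx(hi, abs=0.03)


class TestAnova:
    def test_identical_group_means_give_null(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        f, p = one_way_anova(values, ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)
        f, p = one_way_anova(np.concatenate([x, y]), ["x"] * 20 + ["y"] * 25)
        t, pt_ = sps.ttest_ind(x, y)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt_, rel=1e-10)

    def test_three_groups_match_sum_of_squares_oracle(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(m, 1.3, n) for m, n in [(0, 12), (0.5, 15), (1.1, 9)]]
        values = np.concatenate(groups)
        labels = sum(([f"g{i}"] * len(g) for i, g in enumerate(groups)), [])
        f, p = one_way_anova(values, labels)
        grand = values.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = 2, len(values) - 3
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        assert f == pytest.approx(f_oracle, rel=1e-10)
        assert p == pytest.approx(sps.f.sf(f_oracle, df_b, df_w), rel=1e-10)

    def test_degenerate_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            one_way_anova([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


class TestRelativeRisk:
    def test_identical_proportions_are_unity(self):
        table = summary_from_counts(["a", "b"], [100, 60], [25, 15])
        assert relative_risk(table, "b", "a") == pytest.approx(1.0)

    def test_zero_denominator_events_is_an_error(self):
        table = summary_from_counts(["a", "b"], [100, 60], [0, 15])
        with pytest.raises(ValueError, match="zero events"):
            relative_risk(table, "b", "a")
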