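"""SYNTAX grouping, vessel inclusion and the cohort statistics toolbox."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctffr.cohort_stats import (
    DiagnosticTable,
    VesselRecord,
    anova_oneway,
    chi_square,
    diagnostic_metrics,
    group_event_rates,
    pearson_r,
    roc_auc,
    syntax_group,
    vessel_filter,
)
from ctffr.errors import ValidationError
from ctffr.phantom import CohortSpec, make_cohort


class TestSyntaxGroup:
    @pytest.mark.parametrize("score,label", [
        (0, "low"), (22, "low"), (23, "medium"), (32, "medium"),
        (33, "high"), (50, "high"),
    ])
    def test_boundaries(self, score, label):
        assert syntax_group(score) == label

    def test_fractional_scores_rounded_half_up(self):
        assert syntax_group(22.5) == "medium"
        assert syntax_group(22.4) == "low"
        assert syntax_group(32.5) == "high"

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            syntax_group(-1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 100))
    def test_every_score_in_exactly_one_group(self, score):
        assert syntax_group(score) in ("low", "medium", "high")

    def test_group_sizes_sum_to_n(self):
        df = make_cohort(CohortSpec(n=90, seed=4))
        labels = syntax_group(df["syntax_score"].to_numpy())
        assert sum((labels == g).sum() for g in ("low", "medium", "high")) == 90


class TestVesselFilter:
    def test_boundary_diameter_excluded(self):
        assert vessel_filter([VesselRecord(1.5, 60.0)]) == []

    def test_boundary_stenosis_excluded(self):
        assert vessel_filter([VesselRecord(2.0, 50.0)]) == []

    def test_qualifying_vessel_included_order_preserved(self):
        vs = [VesselRecord(2.0, 80.0), VesselRecord(1.0, 90.0), VesselRecord(3.0, 51.0)]
        out = vessel_filter(vs)
        assert out == [vs[0], vs[2]]

    def test_dataframe_input(self):
        df = pd.DataFrame({"diameter": [1.5, 2.0, 2.5], "stenosis": [60.0, 50.0, 70.0]})
        out = vessel_filter(df)
        assert list(out.index) == [2]


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.random(20)
        r, _, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_scipy_reference(self, rng):
        from scipy import stats

        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        r, ci, p = pearson_r(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        lo, hi = ref.confidence_interval(0.95)
        assert ci[0] == pytest.approx(lo, abs=1e-9)
        assert ci[1] == pytest.approx(hi, abs=1e-9)

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r0, _, _ = pearson_r(x, y)
        r1, _, _ = pearson_r(3 * x + 5, 0.5 * y - 2)
        r2, _, _ = pearson_r(x, -y)
        assert r1 == pytest.approx(r0, rel=1e-9)
        assert r2 == pytest.approx(-r0, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestAnova:
    def test_identical_means_give_near_zero_f(self):
        F, p = anova_oneway([1.0, 2, 3], [2.0, 1, 3], [3.0, 2, 1])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equal_squared_t(self, rng):
        from scipy import stats

        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 12)
        F, p = anova_oneway(a, b)
        t, pt = stats.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        from scipy import stats

        groups = [rng.normal(m, 1, 20) for m in (0.0, 0.3, 0.8)]
        F, p = anova_oneway(*groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_identical_flagged(self):
        F, p = anova_oneway([1.0, 1.0], [1.0, 1.0])
        assert np.isnan(F) and np.isnan(p)


class TestChiSquare:
    def test_independence_expectation_gives_zero(self):
        table = np.outer([30, 70], [0.4, 0.6])
        chi2, p = chi_square(table)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # expected counts all 15 -> chi2 = 4 * (5^2 / 15) = 20/3
        chi2, _ = chi_square([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20 / 3, rel=1e-12)

    def test_matches_scipy_reference(self, rng):
        from scipy import stats

        table = rng.integers(5, 50, size=(3, 2))
        chi2, p = chi_square(table)
        ref = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_scaling_property(self):
        base, _ = chi_square([[10, 20], [20, 10]])
        scaled, _ = chi_square([[30, 60], [60, 30]])
        assert scaled == pytest.approx(3 * base, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[0, 0], [5, 10]])


class TestDiagnostics:
    def test_perfect_classifier(self):
        ffr = np.array([0.6, 0.7, 0.9, 0.95])
        truth = ffr <= 0.8
        table = diagnostic_metrics(ffr, truth)
        assert table.accuracy == 1.0
        assert table.sensitivity == 1.0
        assert table.specificity == 1.0

    def test_all_positive_degenerate(self):
        ffr = np.full(6, 0.5)
        truth = np.array([1, 1, 0, 0, 1, 0], dtype=bool)
        table = diagnostic_metrics(ffr, truth)
        assert table.sensitivity == 1.0
        assert table.specificity == 0.0

    def test_counts_match_direct_arithmetic(self, rng):
        ffr = rng.uniform(0.5, 1.0, 200)
        truth = rng.random(200) < 0.4
        t = diagnostic_metrics(ffr, truth, cutoff=0.8)
        pos = ffr <= 0.8
        assert t.tp == int(np.sum(pos & truth))
        assert t.fp == int(np.sum(pos & ~truth))
        assert t.accuracy == pytest.approx((t.tp + t.tn) / 200)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            diagnostic_metrics(np.array([]), np.array([]))


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0], dtype=bool)
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_chance_level_for_independent_scores(self, rng):
        scores = rng.random(5000)
        labels = rng.random(5000) < 0.5
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_equals_pairwise_concordance(self, rng):
        scores = np.round(rng.random(20), 2)  # force some ties
        labels = rng.random(20) < 0.5
        labels[0] = True
        labels[1] = False
        _, auc = roc_auc(scores, labels)
        pos = scores[labels]
        neg = scores[~labels]
        conc = sum(1.0 if p > q else 0.5 if p == q else 0.0
                   for p in pos for q in neg)
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), rel=1e-12)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        labels[:2] = [True, False]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.array([0.1, 0.2]), np.array([True, True]))


class TestGroupEventRates:
    def test_rates_match_direct_counts(self):
        df = make_cohort(CohortSpec(n=500, seed=9))
        out = group_event_rates(df)
        labels = syntax_group(df["syntax_score"].to_numpy())
        for g in ("low", "medium", "high"):
            sel = labels == g
            assert out["groups"][g]["n"] == int(sel.sum())
            assert out["groups"][g]["events"] == int(df["macce"][sel].sum())

    def test_all_zero_events_degenerate(self):
        df = make_cohort(CohortSpec(n=200, event_probs=(0.0, 0.0, 0.0), seed=1))
        out = group_event_rates(df)
        assert all(v["rate"] == 0 for v in out["groups"].values())
        assert out["overall"]["degenerate"]

    def test_high_group_excess_detected_at_n3000(self):
        df = make_cohort(CohortSpec(n=3000, event_probs=(0.1, 0.1, 0.4), seed=17))
        out = group_event_rates(df)
        assert out["groups"]["high"]["rate"] > out["groups"]["low"]["rate"]
        assert out["pairwise"]["low_vs_high"]["p"] < 0.05
        assert out["pairwise"]["medium_vs_high"]["p"] < 0.05
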