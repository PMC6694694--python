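"""Screening statistics: confusion matrices, kappa, ROC, summary-stats
ANOVA and LSD pairwise comparisons, each checked against an independent
oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fundusdr._exceptions import ContractError, InfiniteFError, UndefinedMetricError
from fundusdr.evaluation import (
    ConfusionMatrix,
    anova_oneway_summary,
    cohen_kappa,
    cohort_summary,
    confusion_matrix,
    format_p,
    kappa_band,
    lsd_pairwise,
    roc_auc,
    screening_metrics,
)


class TestConfusionMatrix:
    def test_identical_pairs_are_diagonal(self):
        cm = confusion_matrix([("a", "a")] * 10, ["a", "b"])
        assert cm.counts[0, 0] == 10
        assert cm.counts.sum() == 10
        assert np.trace(cm.counts) == 10

    def test_grand_total_conserved_and_matches_nested_count(self, rng):
        labels = ["w", "x", "y", "z"]
        pairs = [
            (labels[int(i)], labels[int(j)])
            for i, j in zip(rng.integers(0, 4, 500), rng.integers(0, 4, 500))
        ]
        cm = confusion_matrix(pairs, labels)
        assert cm.total == 500
        # brute-force nested counting oracle
        for i, ref in enumerate(labels):
            for j, test in enumerate(labels):
                expected = sum(1 for p in pairs if p == (ref, test))
                assert cm.counts[i, j] == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ContractError):
            confusion_matrix([("a", "q")], ["a", "b"])


class TestScreeningMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(["neg", "pos"], np.array([[40, 0], [0, 60]]))
        m = screening_metrics(cm, {"pos"})
        assert m.sensitivity == 1 and m.specificity == 1
        assert m.missed_rate == 0 and m.misdiagnosis_rate == 0

    def test_binary_cells_verified_by_direct_count(self):
        # TP=50 FN=5 FP=10 TN=35
        cm = ConfusionMatrix(["neg", "pos"], np.array([[35, 10], [5, 50]]))
        m = screening_metrics(cm, {"pos"})
        assert m.sensitivity == pytest.approx(50 / 55)
        assert m.specificity == pytest.approx(35 / 45)
        assert m.missed_rate == pytest.approx(1 - 50 / 55)
        assert m.misdiagnosis_rate == pytest.approx(1 - 35 / 45)
        assert m.accuracy == pytest.approx(85 / 100)
        assert m.ppv == pytest.approx(50 / 60)
        assert m.npv == pytest.approx(35 / 40)

    def test_multiclass_collapse_matches_brute_force(self, rng):
        labels = ["a", "b", "c", "d"]
        pairs = [
            (labels[int(i)], labels[int(j)])
            for i, j in zip(rng.integers(0, 4, 400), rng.integers(0, 4, 400))
        ]
        cm = confusion_matrix(pairs, labels)
        pos = {"b", "d"}
        m = screening_metrics(cm, pos)
        tp = sum(1 for r, t in pairs if r in pos and t in pos)
        fn = sum(1 for r, t in pairs if r in pos and t not in pos)
        tn = sum(1 for r, t in pairs if r not in pos and t not in pos)
        fp = sum(1 for r, t in pairs if r not in pos and t in pos)
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))

    def test_empty_margin_raises_named_error(self):
        cm = ConfusionMatrix(["neg", "pos"], np.array([[10, 5], [0, 0]]))
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            screening_metrics(cm, {"pos"})


class TestCohenKappa:
    def test_identity_matrix_is_excellent(self):
        cm = ConfusionMatrix(["a", "b", "c"], np.eye(3, dtype=int) * 7)
        kappa, band = cohen_kappa(cm)
        assert kappa == pytest.approx(1.0)
        assert band == "excellent"

    def test_independent_margins_give_zero(self):
        row = np.array([40, 60])
        col = np.array([30, 70])
        counts = np.outer(row, col)  # p_o == p_e by construction
        kappa, _ = cohen_kappa(ConfusionMatrix(["a", "b"], counts))
        assert kappa == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "value,band",
        [(0.1, "poor"), (0.3, "fair"), (0.58, "moderate"), (0.7, "good"), (0.9, "excellent")],
    )
    def test_band_cut_points(self, value, band):
        assert kappa_band(value) == band

    def test_matches_sklearn_on_random_tables(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            counts = rng.integers(0, 30, size=(3, 3))
            counts[0, 0] += 1  # ensure nonzero
            cm = ConfusionMatrix(["a", "b", "c"], counts)
            y1, y2 = [], []
            for i in range(3):
                for j in range(3):
                    y1 += [i] * counts[i, j]
                    y2 += [j] * counts[i, j]
            expected = cohen_kappa_score(y1, y2)
            if np.isnan(expected):
                continue
            kappa, _ = cohen_kappa(cm)
            assert kappa == pytest.approx(expected, abs=1e-12)

    def test_kappa_one_iff_diagonal(self, rng):
        counts = np.diag(rng.integers(1, 20, 4))
        kappa, _ = cohen_kappa(ConfusionMatrix(list("abcd"), counts))
        assert kappa == pytest.approx(1.0)
        counts[0, 1] = 3
        kappa2, _ = cohen_kappa(ConfusionMatrix(list("abcd"), counts))
        assert kappa2 < 1

    def test_degenerate_margins_raise(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[10, 0], [0, 0]]))
        with pytest.raises(UndefinedMetricError):
            cohen_kappa(cm)


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        curve = roc_auc([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(42)
        scores = rng.uniform(size=2000).tolist()
        labels = rng.integers(0, 2, size=2000).tolist()
        curve = roc_auc(scores, labels)
        assert 0.45 <= curve.auc <= 0.55

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        scores = rng.normal(size=100)
        labels = (rng.uniform(size=100) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1  # both classes present
        curve = roc_auc(scores.tolist(), labels.tolist())
        # O(n^2) concordance oracle with half-credit ties
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert curve.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300)
        labels = (scores + rng.normal(size=300) > 0).astype(int)
        curve = roc_auc(scores.tolist(), labels.tolist())
        assert curve.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            roc_auc([0.1, 0.2], [1, 1])


def _raw_anova_oracle(groups_data):
    """scipy f_oneway on raw data reconstructed to match each (n, mean, sd)."""
    arrays = []
    for n, mean, sd in groups_data:
        base = np.arange(n, dtype=np.float64)
        base = (base - base.mean()) / (base.std(ddof=1) or 1.0)
        arrays.append(base * sd + mean)
    return stats.f_oneway(*arrays)


class TestAnovaFromSummaries:
    def test_equal_means_give_zero_f(self):
        res = anova_oneway_summary([(10, 5.0, 1.0), (12, 5.0, 2.0), (8, 5.0, 0.5)])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_equals_raw_data_anova_on_100_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = [
                (int(rng.integers(3, 40)), float(rng.normal(0, 50)), float(rng.uniform(0.5, 30)))
                for _ in range(k)
            ]
            res = anova_oneway_summary(groups)
            oracle = _raw_anova_oracle(groups)
            assert res.F == pytest.approx(oracle.statistic, rel=1e-9)
            assert res.p == pytest.approx(oracle.pvalue, rel=1e-6, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-1000, max_value=1000),
    )
    def test_f_invariant_under_affine_transform(self, a, b):
        groups = [(10, 3.0, 1.5), (15, 7.0, 2.5), (12, 4.0, 1.0)]
        transformed = [(n, a * m + b, a * s) for n, m, s in groups]
        f0 = anova_oneway_summary(groups).F
        f1 = anova_oneway_summary(transformed).F
        assert f1 == pytest.approx(f0, rel=1e-6)

    def test_zero_within_variance_signals_infinite_f(self):
        with pytest.raises(InfiniteFError):
            anova_oneway_summary([(5, 1.0, 0.0), (5, 2.0, 0.0)])

    def test_contract_errors(self):
        with pytest.raises(ContractError):
            anova_oneway_summary([(5, 1.0, 1.0)])
        with pytest.raises(ContractError):
            anova_oneway_summary([(1, 1.0, 1.0), (5, 2.0, 1.0)])


class TestLsdPairwise:
    GROUPS = [(39, 921.05, 1319.560), (29, 15218.59, 17031.178), (23, 16479.22, 15613.505)]

    def test_antisymmetry(self):
        res = anova_oneway_summary(self.GROUPS)
        cmps = lsd_pairwise(res, self.GROUPS)
        by_pair = {c.pair: c for c in cmps}
        for (i, j), c in by_pair.items():
            rev = by_pair[(j, i)]
            assert rev.mean_difference == pytest.approx(-c.mean_difference)
            assert rev.standard_error == pytest.approx(c.standard_error)
            assert rev.p == pytest.approx(c.p)
            assert rev.ci95[0] == pytest.approx(-c.ci95[1])
            assert rev.ci95[1] == pytest.approx(-c.ci95[0])

    def test_se_formula_and_ci_bracket(self):
        res = anova_oneway_summary(self.GROUPS)
        c = next(x for x in lsd_pairwise(res, self.GROUPS) if x.pair == ("group1", "group2"))
        expected_se = np.sqrt(res.ms_within * (1 / 39 + 1 / 29))
        assert c.standard_error == pytest.approx(expected_se, rel=1e-12)
        assert c.ci95[0] <= c.mean_difference <= c.ci95[1]

    def test_matches_raw_data_t_test_with_pooled_error(self, rng):
        groups = [(12, 10.0, 3.0), (15, 14.0, 4.0), (9, 11.0, 2.0)]
        res = anova_oneway_summary(groups)
        c = next(x for x in lsd_pairwise(res, groups) if x.pair == ("group1", "group2"))
        t = c.mean_difference / c.standard_error
        p_oracle = 2 * stats.t.sf(abs(t), res.df_within)
        assert c.p == pytest.approx(p_oracle, rel=1e-12)

    def test_bonferroni_never_smaller_p(self):
        res = anova_oneway_summary(self.GROUPS)
        lsd = {c.pair: c for c in lsd_pairwise(res, self.GROUPS)}
        bon = {c.pair: c for c in lsd_pairwise(res, self.GROUPS, method="bonferroni")}
        for pair in lsd:
            assert bon[pair].p >= lsd[pair].p - 1e-15

    def test_p_display_format(self):
        assert format_p(0.0004) == "< 0.001"
        assert format_p(0.068) == "0.068"


class TestCohortSummary:
    def test_prevalence_matches_brute_force_on_random_tables(self, rng):
        labels = ["none", "mild", "severe", "disq"]
        for _ in range(25):
            counts = rng.integers(0, 50, size=(4, 4))
            counts[0, 0] += 1
            cm = ConfusionMatrix(labels, counts)
            row_totals = counts.sum(axis=1)
            if row_totals[3] == counts.sum():
                continue
            cs = cohort_summary(cm, {"mild", "severe"}, "disq")
            n_qual = counts.sum() - row_totals[3]
            assert cs.n_qualified == n_qual
            assert cs.prevalence_qualified == pytest.approx(
                (row_totals[1] + row_totals[2]) / n_qual
            )

    def test_all_disqualified_raises(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[1, 1] = 10
        cm = ConfusionMatrix(["dr", "disq"], counts)
        with pytest.raises(UndefinedMetricError):
            cohort_summary(cm, {"dr"}, "disq")
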