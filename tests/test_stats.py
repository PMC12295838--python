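"""Confusion metrics, Wilson intervals, McNemar, Pearson and AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from aida_dystocia.stats import (
    ConfusionSummary,
    auc,
    confusion_from_labels,
    confusion_metrics,
    discordant_counts,
    mcnemar,
    pearson,
    wilson_interval,
)


class TestConfusionMetrics:
    def test_all_cesarean_predictions_on_a_mostly_cesarean_stratum(self):
        # e.g. a classifier calling ICD on all 29 classic-stratum cases of
        # which 27 truly were cesareans
        m = confusion_metrics(ConfusionSummary(tp=27, tn=0, fp=2, fn=0))
        assert m["accuracy"] == pytest.approx(27 / 29)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["ppv"] == pytest.approx(27 / 29)
        assert m["npv"] is None  # no negative predictions: undefined, not 0

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionSummary(tp=10, tn=10, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_never_positive_classifier(self):
        m = confusion_metrics(ConfusionSummary(tp=0, tn=5, fp=0, fn=5))
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["ppv"] is None

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionSummary(0, 0, 0, 0))
        with pytest.raises(ValueError):
            ConfusionSummary(-1, 0, 0, 0)

    @settings(derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_accuracy_equals_mean_correctness(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random(30) < 0.5
        truth = rng.random(30) < 0.5
        summary = confusion_from_labels(pred, truth)
        assert confusion_metrics(summary)["accuracy"] == pytest.approx(np.mean(pred == truth))


class TestWilson:
    def test_zero_successes_closed_form(self):
        z = sps.norm.ppf(0.975)
        ci = wilson_interval(0, 10)
        assert ci.lower == 0.0
        assert ci.upper == pytest.approx(z * z / (10 + z * z))

    def test_all_successes_mirrors_zero_case(self):
        lo = wilson_interval(0, 10)
        hi = wilson_interval(10, 10)
        assert hi.upper == 1.0
        assert hi.lower == pytest.approx(1.0 - lo.upper)

    def test_half_successes_symmetric_about_half(self):
        ci = wilson_interval(5, 10)
        assert ci.lower + ci.upper == pytest.approx(1.0)

    def test_matches_reference_implementation(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        for successes, n in [(3, 10), (19, 20), (40, 66), (60, 66), (1, 135)]:
            ci = wilson_interval(successes, n)
            lo, up = statsmodels.proportion_confint(successes, n, alpha=0.05, method="wilson")
            assert ci.lower == pytest.approx(lo)
            assert ci.upper == pytest.approx(up)

    @settings(derandomize=True)
    @given(n=st.integers(1, 500), frac=st.floats(0.0, 1.0))
    def test_interval_within_unit_range_and_shrinks_with_n(self, n, frac):
        successes = round(frac * n)
        ci = wilson_interval(successes, n)
        assert 0.0 <= ci.lower <= ci.upper <= 1.0
        wider = wilson_interval(successes * 4, n * 4)
        assert (wider.upper - wider.lower) <= (ci.upper - ci.lower) + 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 4)


class TestMcNemar:
    def test_balanced_discordance_uncorrected(self):
        res = mcnemar(7, 7, corrected=False)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_uncorrected_statistic_value(self):
        res = mcnemar(10, 2, corrected=False)
        assert res.chi2 == pytest.approx(64 / 12)

    def test_continuity_correction_kills_small_imbalance(self):
        res = mcnemar(2, 1, corrected=True)
        assert res.chi2 == 0.0

    def test_degenerate_zero_discordance(self):
        res = mcnemar(0, 0)
        assert res.degenerate and res.chi2 == 0.0 and res.p == 1.0

    @settings(derandomize=True)
    @given(b=st.integers(0, 50), c=st.integers(0, 50), corrected=st.booleans())
    def test_symmetric_in_b_and_c(self, b, c, corrected):
        r1, r2 = mcnemar(b, c, corrected), mcnemar(c, b, corrected)
        assert r1.chi2 == pytest.approx(r2.chi2) and r1.p == pytest.approx(r2.p)

    def test_matches_reference_implementation(self):
        ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c, corrected in [(10, 2, False), (10, 2, True), (5, 9, True)]:
            ours = mcnemar(b, c, corrected)
            ref = ct.mcnemar([[0, b], [c, 0]], exact=False, correction=corrected)
            assert ours.chi2 == pytest.approx(float(ref.statistic))
            assert ours.p == pytest.approx(float(ref.pvalue))

    def test_discordant_counts_from_predictions(self):
        truth = [True, True, True, False]
        a = [True, True, False, False]  # right on 1,2,4
        b = [True, False, True, True]  # right on 1,3
        assert discordant_counts(a, b, truth) == (2, 1)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 1000), a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0))
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.random(20), rng.random(20)
        r0 = pearson(x, y)[0]
        assert pearson(a * x + b, y)[0] == pytest.approx(r0)
        assert pearson(-a * x + b, y)[0] == pytest.approx(-r0)

    def test_recovers_population_correlation_by_simulation(self):
        # moderate positive correlation of the size seen between midline
        # angle and head-symphysis distance
        rho = 0.36
        rng = np.random.default_rng(42)
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=20_000)
        r, p = pearson(xy[:, 0], xy[:, 1])
        # 4 standard errors of r at this n
        se = (1 - rho**2) / np.sqrt(20_000)
        assert abs(r - rho) < 4 * se
        assert p < 1e-6


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True]) == 1.0

    def test_all_scores_tied(self):
        assert auc([0.5] * 6, [True, False, True, False, True, False]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [True, True])

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 200))
    def test_matches_pairwise_comparison_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 10, size=n) / 10.0  # force ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        assert abs(auc(scores, labels) - 0.5) < 0.05
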