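"""Seeded splitting, backend training and recorded-prediction scoring."""

import numpy as np
import pytest

from aida_dystocia.cohort import BinaryOutcome, CaseRecord, Cohort, DeliveryOutcome
from aida_dystocia.core import ColorCode, ColorPattern, GeometricProfile
from aida_dystocia.geometry import Stratum
from aida_dystocia.ml import (
    ALGORITHMS,
    FeatureEncoding,
    MissingFeatureError,
    SplitConfig,
    multi_seed_evaluate,
    score_recorded_predictions,
    split_cohort,
    train_and_predict,
    train_test_sizes,
)
from aida_dystocia.simulate import default_config, generate_cohort
from aida_dystocia.stats import confusion_metrics

pytestmark = pytest.mark.filterwarnings("ignore::FutureWarning")

G, R = ColorCode.GREEN, ColorCode.RED


def _separable_cohort(n=40):
    """Cesarean iff AoP is small: linearly separable in RAW features."""
    cases = []
    for i in range(n):
        cesarean = i % 2 == 0
        aop = 90.0 + i * 0.1 if cesarean else 150.0 + i * 0.1
        cases.append(
            CaseRecord(
                patient_id=f"p{i}",
                mla_deg=80.0,
                colors=ColorPattern(R, R, R, R),
                outcome=DeliveryOutcome(
                    BinaryOutcome.CESAREAN if cesarean else BinaryOutcome.VAGINAL
                ),
                raw_profile=GeometricProfile(aop=aop, hsd=20.0, mla=80.0, ad=10.0),
            )
        )
    return Cohort(cases)


@pytest.mark.parametrize(
    ("n", "expected"), [(135, (95, 40)), (10, (7, 3)), (66, (46, 20)), (2, (1, 1))]
)
def test_train_test_sizes(n, expected):
    assert train_test_sizes(n, 0.7) == expected


def test_split_is_deterministic_conserving_and_disjoint():
    cohort = _separable_cohort(33)
    cfg = SplitConfig()
    train1, test1 = split_cohort(cohort, cfg, seed=250)
    train2, test2 = split_cohort(cohort, cfg, seed=250)
    assert [c.patient_id for c in train1] == [c.patient_id for c in train2]
    assert len(train1) + len(test1) == len(cohort)
    ids = {c.patient_id for c in train1} | {c.patient_id for c in test1}
    assert len(ids) == len(cohort)
    # a different seed gives a different partition
    train3, _ = split_cohort(cohort, cfg, seed=500)
    assert [c.patient_id for c in train1] != [c.patient_id for c in train3]


def test_stratified_split_preserves_class_balance():
    cohort = _separable_cohort(40)  # 20/20 outcome balance
    train, test = split_cohort(cohort, SplitConfig(stratify=True), seed=1)
    y_train = [c.is_cesarean for c in train]
    assert sum(y_train) == 14 and len(train) == 28


@pytest.mark.parametrize("backend", ALGORITHMS)
def test_separable_data_predicted_perfectly(backend):
    cohort = _separable_cohort(40)
    train, test = split_cohort(cohort, SplitConfig(), seed=1)
    preds = train_and_predict(backend, train, test, FeatureEncoding.RAW, seed=1)
    truth = {c.patient_id: c.is_cesarean for c in test}
    assert all((lab == "ICD") == truth[pid] for pid, lab in zip(preds.patient_ids, preds.labels))


def test_single_class_training_set_rejected():
    cohort = _separable_cohort(10)
    all_pos = cohort.subset(lambda c: c.is_cesarean)
    with pytest.raises(ValueError, match="single outcome class"):
        train_and_predict("RF", all_pos, cohort, FeatureEncoding.RAW, seed=0)


def test_missing_raw_features_instructs_fallback(fixture_cohort):
    train, test = split_cohort(fixture_cohort, SplitConfig(), seed=1)
    with pytest.raises(MissingFeatureError, match="COLOR_ORDINAL"):
        train_and_predict("RF", train, test, FeatureEncoding.RAW, seed=1)


def test_repeated_run_is_identical(fixture_cohort):
    train, test = split_cohort(fixture_cohort, SplitConfig(), seed=0)
    a = train_and_predict("MLP", train, test, FeatureEncoding.COLOR_ORDINAL, seed=0)
    b = train_and_predict("MLP", train, test, FeatureEncoding.COLOR_ORDINAL, seed=0)
    assert a.labels == b.labels
    assert np.array_equal(a.scores, b.scores)
    assert a.to_dataframe().to_csv() == b.to_dataframe().to_csv()


def test_multi_seed_evaluation_cardinality_and_means(fixture_cohort):
    cfg = SplitConfig(seeds=(1, 0, 250, 500, 750))
    results = multi_seed_evaluate(fixture_cohort, cfg, backends=("RF",))
    evaluation = results["RF"]
    assert sorted(evaluation.per_seed) == [0, 1, 250, 500, 750]
    accs = [confusion_metrics(s)["accuracy"] for s in evaluation.per_seed.values()]
    assert evaluation.mean_metrics["accuracy"] == pytest.approx(np.mean(accs))
    for summary in evaluation.per_seed.values():
        assert summary.total == 20  # 30% of 66


def test_no_signal_cohort_accuracy_near_majority_rate():
    """With outcome independent of features, test accuracy stays within
    Monte-Carlo noise of the majority-class rate."""
    cfg = default_config(n=400, seed=11)
    cfg.cd_prob = {k: 0.75 for k in range(5)}  # class carries no information
    cohort = generate_cohort(cfg)
    results = multi_seed_evaluate(
        cohort, SplitConfig(seeds=(1, 0, 250)), backends=("RF",), encoding=FeatureEncoding.RAW
    )
    mean_acc = results["RF"].mean_metrics["accuracy"]
    n_eval = 120 * 3
    se = np.sqrt(0.75 * 0.25 / n_eval)
    assert abs(mean_acc - 0.75) < 5 * se


class TestRecordedPredictionScoring:
    def test_classic_stratum_svm_confusion(self, fixture_cohort):
        s = score_recorded_predictions(fixture_cohort, "SVM", stratum=Stratum.CLASSIC)
        assert (s.tp, s.tn, s.fp, s.fn) == (27, 0, 2, 0)
        assert confusion_metrics(s)["accuracy"] == pytest.approx(27 / 29)

    @pytest.mark.parametrize(
        ("stratum", "algo", "pct"),
        [
            (Stratum.CLASSIC, "SVM", 93.1),
            (Stratum.CLASSIC, "RF", 93.1),
            (Stratum.CLASSIC, "MLP", 89.7),
            (Stratum.NEAR, "SVM", 100.0),
            (Stratum.NEAR, "RF", 100.0),
            (Stratum.NEAR, "MLP", 100.0),
            (Stratum.TRANSITIONAL, "SVM", 89.3),
            (Stratum.TRANSITIONAL, "RF", 92.9),
            (Stratum.TRANSITIONAL, "MLP", 78.6),
        ],
    )
    def test_per_stratum_recorded_accuracies(self, fixture_cohort, stratum, algo, pct):
        s = score_recorded_predictions(fixture_cohort, algo, stratum=stratum)
        assert round(100 * confusion_metrics(s)["accuracy"], 1) == pct

    def test_class_restricted_scoring(self, fixture_cohort):
        # every class-4 case was a cesarean and SVM/RF called them all
        for algo in ("SVM", "RF"):
            s = score_recorded_predictions(fixture_cohort, algo, aida_class=4)
            assert s.total == 21 and s.tp == 21

    def test_unknown_algorithm_rejected(self, fixture_cohort):
        with pytest.raises(ValueError):
            score_recorded_predictions(fixture_cohort, "GBM")

    def test_empty_subset_rejected(self, fixture_cohort):
        with pytest.raises(ValueError, match="no cases"):
            score_recorded_predictions(fixture_cohort, "RF", stratum=Stratum.OTHER)
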