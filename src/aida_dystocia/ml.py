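"""Seeded train/test machine-learning stage and recorded-prediction scoring.

Three pluggable binary classifier backends — a support vector machine, a
random forest and a multilayer perceptron — predict cesarean delivery
from case features under a 70/30 split repeated over a list of seeds
(default 1, 0, 250, 500, 750). Every source of randomness receives the
run seed, so a run is fully reproducible from its manifest.

Two evaluation routes exist and must not be confused:

* retraining (:func:`train_and_predict`, :func:`multi_seed_evaluate`)
  fits fresh models on a cohort;
* recorded-prediction scoring (:func:`score_recorded_predictions`)
  compares the prediction columns already present in a cohort — e.g. the
  published per-case SVM/RF/MLP calls of the packaged fixture — against
  outcomes, with no model fitting at all.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import ALGORITHMS, CaseRecord, Cohort
from .geometry import canonical_mla, Stratum
from .stats import ConfusionSummary, confusion_from_labels, confusion_metrics

DEFAULT_SEEDS = (1, 0, 250, 500, 750)


class FeatureEncoding(enum.Enum):
    #: four raw geometric measurements (requires raw profiles)
    RAW = "RAW"
    #: per-parameter ordinal color (GREEN=0, YELLOW=1, RED=2) plus canonical MLA degrees
    COLOR_ORDINAL = "COLOR_ORDINAL"
    #: the AIDA class alone
    CLASS_ONLY = "CLASS_ONLY"


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.7
    seeds: tuple[int, ...] = DEFAULT_SEEDS
    stratify: bool = False
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.seeds:
            raise ValueError("need at least one seed")


@dataclass
class PredictionSet:
    algorithm: str
    seed: int
    encoding: FeatureEncoding
    patient_ids: list[str]
    scores: np.ndarray  # P(cesarean)
    labels: list[str]  # ICD / NOICD

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "algorithm": self.algorithm,
                "seed": self.seed,
                "score": self.scores,
                "label": self.labels,
            }
        )


class MissingFeatureError(ValueError):
    pass


def encode_features(cohort: Cohort, encoding: FeatureEncoding) -> np.ndarray:
    """Design matrix for a cohort under the chosen encoding."""
    rows = []
    for rec in cohort:
        if encoding is FeatureEncoding.RAW:
            if rec.raw_profile is None:
                raise MissingFeatureError(
                    f"patient {rec.patient_id}: no raw profile; use COLOR_ORDINAL encoding"
                )
            p = rec.raw_profile
            rows.append([p.aop, p.hsd, canonical_mla(p.mla).value, p.ad])
        elif encoding is FeatureEncoding.COLOR_ORDINAL:
            rows.append(
                [
                    rec.colors.aop.risk_rank,
                    rec.colors.hsd.risk_rank,
                    rec.colors.mla.risk_rank,
                    rec.colors.ad.risk_rank,
                    canonical_mla(rec.mla_deg).value,
                ]
            )
        else:
            rows.append([rec.aida_class])
    return np.asarray(rows, dtype=float)


def outcome_vector(cohort: Cohort) -> np.ndarray:
    return np.asarray([rec.is_cesarean for rec in cohort], dtype=bool)


def train_test_sizes(n: int, train_fraction: float) -> tuple[int, int]:
    """Round-half-up train size; e.g. n=135 at 0.7 gives (95, 40)."""
    n_train = int(math.floor(n * train_fraction + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    return n_train, n - n_train


def split_cohort(cohort: Cohort, cfg: SplitConfig, seed: int) -> tuple[Cohort, Cohort]:
    """Deterministic random partition given (cohort order, seed)."""
    n = len(cohort)
    if n < 2:
        raise ValueError("cohort must have at least 2 cases to split")
    n_train, _ = train_test_sizes(n, cfg.train_fraction)
    rng = np.random.default_rng(seed)
    if cfg.stratify:
        y = outcome_vector(cohort)
        train_idx: list[int] = []
        for value in (True, False):
            idx = np.flatnonzero(y == value)
            k = int(math.floor(len(idx) * cfg.train_fraction + 0.5))
            train_idx.extend(rng.permutation(idx)[:k].tolist())
        train_set = set(train_idx)
    else:
        perm = rng.permutation(n)
        train_set = set(perm[:n_train].tolist())
    cases = list(cohort)
    train = [cases[i] for i in range(n) if i in train_set]
    test = [cases[i] for i in range(n) if i not in train_set]
    return (
        Cohort(train, provenance=cohort.provenance),
        Cohort(test, provenance=cohort.provenance),
    )


def _make_backend(name: str, seed: int):
    if name == "SVM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(probability=True, random_state=seed)),
            ]
        )
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    if name == "MLP":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", MLPClassifier(random_state=seed, max_iter=2000)),
            ]
        )
    raise ValueError(f"unknown backend {name!r}; choose from {ALGORITHMS}")


def train_and_predict(
    backend: str,
    train: Cohort,
    test: Cohort,
    encoding: FeatureEncoding = FeatureEncoding.COLOR_ORDINAL,
    seed: int = 0,
    decision_threshold: float = 0.5,
) -> PredictionSet:
    """Fit one backend on the training part and score the test part."""
    y_train = outcome_vector(train)
    if y_train.all() or not y_train.any():
        raise ValueError("training set contains a single outcome class; cannot fit")
    X_train = encode_features(train, encoding)
    X_test = encode_features(test, encoding)
    model = _make_backend(backend, seed)
    model.fit(X_train, y_train.astype(int))
    scores = model.predict_proba(X_test)[:, list(model.classes_).index(1)]
    labels = ["ICD" if s >= decision_threshold else "NOICD" for s in scores]
    return PredictionSet(
        algorithm=backend,
        seed=seed,
        encoding=encoding,
        patient_ids=[rec.patient_id for rec in test],
        scores=scores,
        labels=labels,
    )


@dataclass
class BackendEvaluation:
    backend: str
    per_seed: dict[int, ConfusionSummary] = field(default_factory=dict)

    @property
    def mean_metrics(self) -> dict[str, float]:
        """Unweighted mean over seeds of each defined metric."""
        acc: dict[str, list[float]] = {}
        for summary in self.per_seed.values():
            for key, value in confusion_metrics(summary).items():
                if value is not None:
                    acc.setdefault(key, []).append(value)
        return {key: float(np.mean(vals)) for key, vals in acc.items()}


def multi_seed_evaluate(
    cohort: Cohort,
    cfg: SplitConfig,
    backends: Sequence[str] = ALGORITHMS,
    encoding: FeatureEncoding = FeatureEncoding.COLOR_ORDINAL,
) -> dict[str, BackendEvaluation]:
    """Per-(backend, seed) test-set confusion summaries plus seed means."""
    results = {name: BackendEvaluation(backend=name) for name in backends}
    for seed in cfg.seeds:
        train, test = split_cohort(cohort, cfg, seed)
        y_test = outcome_vector(test)
        for name in backends:
            preds = train_and_predict(
                name, train, test, encoding, seed, cfg.decision_threshold
            )
            pred_pos = np.asarray([lab == "ICD" for lab in preds.labels])
            results[name].per_seed[seed] = confusion_from_labels(pred_pos, y_test)
    return results


def score_recorded_predictions(
    cohort: Cohort,
    algorithm: str,
    stratum: Optional[Stratum] = None,
    aida_class: Optional[int] = None,
) -> ConfusionSummary:
    """Score a cohort's recorded prediction column against its outcomes.

    No model is fitted. Optionally restricts to one transverse stratum
    and/or one AIDA class.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")

    def keep(rec: CaseRecord) -> bool:
        if rec.recorded_predictions is None:
            raise ValueError(f"patient {rec.patient_id}: no recorded predictions")
        if stratum is not None and rec.stratum is not stratum:
            return False
        if aida_class is not None and rec.aida_class != aida_class:
            return False
        return True

    cases = [rec for rec in cohort if keep(rec)]
    if not cases:
        raise ValueError("no cases match the requested subset")
    pred_pos = [rec.recorded_predictions[algorithm] == "ICD" for rec in cases]
    truth = [rec.is_cesarean for rec in cases]
    return confusion_from_labels(pred_pos, truth)
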