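"""Statistical evaluation toolkit.

Confusion-matrix metric family, Wilson score intervals for proportions,
McNemar's paired test for comparing two classifiers on the same cases,
Pearson correlation, and rank-based AUC. The positive class throughout is
cesarean delivery (ICD).

Metrics with a zero denominator are reported as ``None`` (undefined), not
coerced to 0 — specificity on an all-cesarean stratum has no value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionSummary:
    """Binary confusion counts; positive class = cesarean/ICD."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class WilsonInterval:
    point: float
    lower: float
    upper: float
    confidence: float


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    chi2: float
    p: float
    corrected: bool
    degenerate: bool = False


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(s: ConfusionSummary) -> dict[str, Optional[float]]:
    """Accuracy, sensitivity, specificity, PPV, NPV and F1 from counts.

    Undefined metrics (zero denominator) come back as None.
    """
    if s.total == 0:
        raise ValueError("empty confusion summary")
    ppv = _ratio(s.tp, s.tp + s.fp)
    sens = _ratio(s.tp, s.tp + s.fn)
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    return {
        "accuracy": (s.tp + s.tn) / s.total,
        "sensitivity": sens,
        "specificity": _ratio(s.tn, s.tn + s.fp),
        "ppv": ppv,
        "npv": _ratio(s.tn, s.tn + s.fn),
        "f1": f1,
    }


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> WilsonInterval:
    """Wilson score interval for a binomial proportion.

    Uses the exact normal quantile for the stated confidence (not a
    rounded 1.96).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= successes <= n):
        raise ValueError(f"successes {successes} outside [0, {n}]")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    z = sps.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    # exact endpoints: the score bound is analytically 0 (resp. 1) there
    lower = 0.0 if successes == 0 else max(0.0, center - half)
    upper = 1.0 if successes == n else min(1.0, center + half)
    return WilsonInterval(point=phat, lower=lower, upper=upper, confidence=confidence)


def mcnemar(b: int, c: int, corrected: bool = True) -> McNemarResult:
    """McNemar's chi-square test from discordant-pair counts b and c.

    ``corrected`` applies the Edwards continuity correction
    (|b - c| - 1)^2 / (b + c); the uncorrected statistic is
    (b - c)^2 / (b + c). b + c = 0 is degenerate and reported as
    chi2 = 0, p = 1 with the flag set.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return McNemarResult(b=b, c=c, chi2=0.0, p=1.0, corrected=corrected, degenerate=True)
    diff = abs(b - c)
    if corrected:
        diff = max(0.0, diff - 1.0)
    chi2 = diff * diff / (b + c)
    p = float(sps.chi2.sf(chi2, df=1))
    return McNemarResult(b=b, c=c, chi2=float(chi2), p=p, corrected=corrected)


def discordant_counts(pred_a: Sequence[bool], pred_b: Sequence[bool], truth: Sequence[bool]) -> tuple[int, int]:
    """(b, c) = cases a-correct/b-wrong and a-wrong/b-correct."""
    a = np.asarray(pred_a, dtype=bool)
    bb = np.asarray(pred_b, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if not (len(a) == len(bb) == len(t)):
        raise ValueError("prediction and truth vectors must have equal length")
    a_ok = a == t
    b_ok = bb == t
    return int(np.sum(a_ok & ~b_ok)), int(np.sum(~a_ok & b_ok))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based (Mann-Whitney) AUC; ties counted half."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels.astype(int), scores))


def confusion_from_labels(pred_positive: Sequence[bool], true_positive: Sequence[bool]) -> ConfusionSummary:
    p = np.asarray(pred_positive, dtype=bool)
    t = np.asarray(true_positive, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("prediction and truth vectors must have equal length")
    return ConfusionSummary(
        tp=int(np.sum(p & t)),
        tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
    )
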