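"""One-shot recomputation of the headline study-cohort results.

Every number here is recomputed at run time from the packaged 66-case
cohort by the geometry, classification, analysis and scoring modules;
:data:`REFERENCE` holds the corresponding published values so the CLI can
print a PASS/FAIL comparison. Percentages are rounded to one decimal,
matching the published printing convention.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .analysis import class_cd_rates, class_totals, color_distribution, stratified_cd_rates, stratum_totals
from .cohort import ALGORITHMS, Cohort, load_fixture
from .geometry import Stratum
from .ml import score_recorded_predictions
from .stats import confusion_metrics

#: Published values for each headline quantity (percent, one decimal).
REFERENCE: dict[str, float] = {
    "stratum_count_classic": 29,
    "stratum_count_near": 9,
    "stratum_count_transitional": 28,
    "stratum_pct_classic": 43.9,
    "stratum_pct_near": 13.6,
    "stratum_pct_transitional": 42.4,
    "cd_rate_pct_classic": 93.1,
    "cd_rate_pct_near": 100.0,
    "cd_rate_pct_transitional": 85.7,
    "class3_cd_rate_pct": 90.6,
    "class4_cd_rate_pct": 100.0,
    "class_total_0": 1,
    "class_total_1": 2,
    "class_total_2": 10,
    "class_total_3": 32,
    "class_total_4": 21,
    "class3_pct_classic": 55.2,
    "accuracy_pct_classic_SVM": 93.1,
    "accuracy_pct_classic_RF": 93.1,
    "accuracy_pct_classic_MLP": 89.7,
    "accuracy_pct_near_SVM": 100.0,
    "accuracy_pct_near_RF": 100.0,
    "accuracy_pct_near_MLP": 100.0,
    "accuracy_pct_transitional_SVM": 89.3,
    "accuracy_pct_transitional_RF": 92.9,
    "accuracy_pct_transitional_MLP": 78.6,
    "mla_red_pct_classic": 100.0,
    "mla_red_pct_near": 100.0,
    "aop_red_pct_classic": 86.2,
    "aop_red_pct_near": 77.8,
    "aop_red_pct_transitional": 78.6,
    "spd_red_pct_classic": 86.2,
    "spd_red_pct_near": 66.7,
    "spd_red_pct_transitional": 71.4,
    "ad_red_or_yellow_pct_classic": 44.8,
    "ad_red_or_yellow_pct_near": 55.6,
    "ad_red_or_yellow_pct_transitional": 50.0,
}

_STRATA = {
    "classic": Stratum.CLASSIC,
    "near": Stratum.NEAR,
    "transitional": Stratum.TRANSITIONAL,
}


def _pct(x: float) -> float:
    return round(100.0 * x, 1)


def headline_results(cohort: Optional[Cohort] = None) -> dict[str, float]:
    """Recompute every headline quantity from a cohort (default: fixture)."""
    if cohort is None:
        cohort = load_fixture()
    n = len(cohort)
    out: dict[str, float] = {}

    counts = stratum_totals(cohort)
    for name, stratum in _STRATA.items():
        out[f"stratum_count_{name}"] = int(counts[stratum.value])
        out[f"stratum_pct_{name}"] = _pct(counts[stratum.value] / n)

    rates = stratified_cd_rates(cohort)
    for name, stratum in _STRATA.items():
        out[f"cd_rate_pct_{name}"] = _pct(rates.loc[stratum.value, "rate"])

    by_class = class_cd_rates(cohort)
    out["class3_cd_rate_pct"] = _pct(by_class.loc[3, "rate"])
    out["class4_cd_rate_pct"] = _pct(by_class.loc[4, "rate"])
    totals = class_totals(cohort)
    for k in range(5):
        out[f"class_total_{k}"] = int(totals[k])

    classic = cohort.subset(lambda rec: rec.stratum is Stratum.CLASSIC)
    n_class3 = sum(1 for rec in classic if rec.aida_class == 3)
    out["class3_pct_classic"] = _pct(n_class3 / len(classic))

    for name, stratum in _STRATA.items():
        for algo in ALGORITHMS:
            summary = score_recorded_predictions(cohort, algo, stratum=stratum)
            out[f"accuracy_pct_{name}_{algo}"] = _pct(confusion_metrics(summary)["accuracy"])

    colors = color_distribution(cohort)
    for name, stratum in _STRATA.items():
        key = stratum.value
        if name in ("classic", "near"):
            out[f"mla_red_pct_{name}"] = _pct(colors.loc[("mla", key), "red"])
        out[f"aop_red_pct_{name}"] = _pct(colors.loc[("aop", key), "red"])
        out[f"spd_red_pct_{name}"] = _pct(colors.loc[("hsd", key), "red"])
        out[f"ad_red_or_yellow_pct_{name}"] = _pct(colors.loc[("ad", key), "red_or_yellow"])
    return out


def reproduction_report(cohort: Optional[Cohort] = None) -> pd.DataFrame:
    """Computed vs published values with a PASS/FAIL flag per quantity."""
    computed = headline_results(cohort)
    rows = []
    for key, ref in REFERENCE.items():
        value = computed[key]
        rows.append(
            {
                "quantity": key,
                "computed": value,
                "published": ref,
                "status": "PASS" if float(value) == float(ref) else "FAIL",
            }
        )
    return pd.DataFrame(rows)
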