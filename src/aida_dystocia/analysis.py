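"""Descriptive results engine for a classified cohort.

Stratified cesarean rates across the transverse spectrum, per-class risk
profiles, the class x stratum x outcome cross-tabulation, per-parameter
color distributions, and the profile of vaginal-delivery cases.

Rates are reported as exact fractions (k/n) alongside percentages rounded
to one decimal. Empty strata or classes yield NaN rates, never 0%, so
risk gradients on small cohorts stay honest.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort
from .core import ColorCode, PARAMETERS
from .geometry import Stratum
from .stats import wilson_interval

#: Gradient order used in reports: highest observed risk first.
GRADIENT_ORDER = (Stratum.NEAR, Stratum.CLASSIC, Stratum.TRANSITIONAL, Stratum.OTHER)

_COLOR_COLUMNS = {"aop": "aida_aop", "hsd": "aida_spd", "mla": "aida_mla", "ad": "aida_ad"}


def _case_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        rows.append(
            {
                "patient_id": rec.patient_id,
                "stratum": rec.stratum.value,
                "aida_class": rec.aida_class,
                "cesarean": rec.is_cesarean,
                "aop": rec.colors.aop.value,
                "hsd": rec.colors.hsd.value,
                "mla": rec.colors.mla.value,
                "ad": rec.colors.ad.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "stratum", "aida_class", "cesarean", "aop", "hsd", "mla", "ad"],
    )


def _rate_row(n: int, k: int, confidence: Optional[float]) -> dict[str, object]:
    row: dict[str, object] = {
        "n": n,
        "cesarean": k,
        "rate": k / n if n else np.nan,
        "percent": round(100.0 * k / n, 1) if n else np.nan,
    }
    if confidence is not None:
        if n:
            ci = wilson_interval(k, n, confidence)
            row["ci_lower"], row["ci_upper"] = ci.lower, ci.upper
        else:
            row["ci_lower"] = row["ci_upper"] = np.nan
    return row


def stratified_cd_rates(cohort: Cohort, confidence: Optional[float] = None) -> pd.DataFrame:
    """Cesarean rate per transverse stratum, in risk-gradient order."""
    df = _case_frame(cohort)
    rows = {}
    for stratum in GRADIENT_ORDER:
        sub = df[df["stratum"] == stratum.value]
        rows[stratum.value] = _rate_row(len(sub), int(sub["cesarean"].sum()), confidence)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "stratum"
    return out


def class_cd_rates(cohort: Cohort, confidence: Optional[float] = None) -> pd.DataFrame:
    """Cesarean rate per AIDA class 0..4."""
    df = _case_frame(cohort)
    rows = {}
    for k in range(5):
        sub = df[df["aida_class"] == k]
        rows[k] = _rate_row(len(sub), int(sub["cesarean"].sum()), confidence)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "aida_class"
    return out


def crosstab(cohort: Cohort) -> pd.DataFrame:
    """Counts indexed by (AIDA class, stratum) with outcome columns and margins.

    Columns: cesarean, vaginal, total; the grand total equals the cohort
    size by construction.
    """
    df = _case_frame(cohort)
    if df.empty:
        return pd.DataFrame(columns=["cesarean", "vaginal", "total"])
    tab = (
        df.groupby(["aida_class", "stratum"])["cesarean"]
        .agg(total="size", cesarean="sum")
        .reset_index()
    )
    tab["vaginal"] = tab["total"] - tab["cesarean"]
    return tab.set_index(["aida_class", "stratum"])[["cesarean", "vaginal", "total"]]


def class_totals(cohort: Cohort) -> pd.Series:
    """Cases per AIDA class 0..4."""
    df = _case_frame(cohort)
    counts = df["aida_class"].value_counts()
    return pd.Series([int(counts.get(k, 0)) for k in range(5)], index=range(5), name="n")


def stratum_totals(cohort: Cohort) -> pd.Series:
    df = _case_frame(cohort)
    return pd.Series(
        {s.value: int((df["stratum"] == s.value).sum()) for s in GRADIENT_ORDER}, name="n"
    )


def color_distribution(cohort: Cohort) -> pd.DataFrame:
    """Per-parameter, per-stratum color fractions.

    One row per (parameter, stratum) with the fraction of each color, the
    combined RED-or-YELLOW fraction, and the group size. Empty strata are
    omitted.
    """
    df = _case_frame(cohort)
    rows = []
    for param in PARAMETERS:
        for stratum in GRADIENT_ORDER:
            sub = df[df["stratum"] == stratum.value]
            if sub.empty:
                continue
            n = len(sub)
            frac = {
                color.value.lower(): float((sub[param] == color.value).sum()) / n
                for color in ColorCode
            }
            rows.append(
                {
                    "parameter": param,
                    "stratum": stratum.value,
                    "n": n,
                    **frac,
                    "red_or_yellow": frac["red"] + frac["yellow"],
                }
            )
    return pd.DataFrame(rows).set_index(["parameter", "stratum"])


def vaginal_profile(cohort: Cohort) -> pd.DataFrame:
    """Vaginal-delivery cases with stratum, class and green-parameter count.

    The returned frame carries ``frac_with_green`` in ``.attrs``: the
    fraction of vaginal cases with at least one GREEN parameter.
    """
    rows = []
    for rec in cohort:
        if rec.is_cesarean:
            continue
        n_green = sum(1 for c in rec.colors if c is ColorCode.GREEN)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "stratum": rec.stratum.value,
                "aida_class": rec.aida_class,
                "n_green": n_green,
                "has_green": n_green >= 1,
            }
        )
    out = pd.DataFrame(rows, columns=["patient_id", "stratum", "aida_class", "n_green", "has_green"])
    out.attrs["frac_with_green"] = float(out["has_green"].mean()) if len(out) else np.nan
    return out
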