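"""Case records, cohort CSV I/O and the packaged 66-case study cohort.

A :class:`CaseRecord` is one labor case: the midline angle in degrees, the
four AIDA color codes, the delivery outcome (binary cesarean/vaginal, with
the detailed category when known) and, optionally, the recorded
predictions of the three machine-learning algorithms and a raw geometric
profile. A :class:`Cohort` is an ordered collection of cases with unique
patient ids and a provenance tag.

The packaged fixture is the published 66-case transverse-position cohort
(per-case midline angle, color codes, recorded AIDA class, delivery
outcome and recorded SVM/RF/MLP predictions), shipped as CSV with a
checksum. The detailed outcome category of each individual case was never
published, so per-case records carry the binary outcome only; the
published class-by-stratum breakdown of detailed outcomes ships separately
as an aggregate table (:func:`load_outcome_totals`).

CSV dialect: comma-separated, UTF-8, header mandatory, colors as
GREEN/YELLOW/RED, outcomes as ICD/NOICD (or a detailed label). The HSD
color column is named ``aida_spd`` — "SPD" is the alias the source tables
use for the head-symphysis distance.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from .core import ColorCode, ColorPattern, GeometricProfile, assign_aida_class
from .geometry import canonical_mla, stratum_from_canonical, Stratum

FIXTURE_FILENAME = "transverse_cohort.csv"
FIXTURE_SHA256 = "631665e6ce23cb0340a913de16d78c3bfc35c2c03d02895d7f08ddd0a6381c9d"
OUTCOME_TOTALS_FILENAME = "class_stratum_outcome_totals.csv"
OUTCOME_TOTALS_SHA256 = "71ebe3012cc3a773b6780a68343ec81b019171a7639d34ad0416796533f5e6a6"

ALGORITHMS = ("SVM", "RF", "MLP")

REQUIRED_COLUMNS = (
    "patient_id",
    "mla_deg",
    "delivery_outcome",
    "aida_mla",
    "aida_aop",
    "aida_spd",
    "aida_ad",
)
PREDICTION_COLUMNS = {"SVM": "pred_svm", "RF": "pred_rf", "MLP": "pred_mlp"}
RAW_COLUMNS = ("aop", "hsd", "ad")  # raw mla is mla_deg itself


class CohortValidationError(ValueError):
    """Raised on malformed cohort files; messages are row-addressed."""


class FixtureIntegrityError(RuntimeError):
    """Packaged data does not match its recorded checksum."""


class BinaryOutcome(enum.Enum):
    CESAREAN = "CESAREAN"
    VAGINAL = "VAGINAL"


class DetailedOutcome(enum.Enum):
    SPONTANEOUS = "SPONTANEOUS"
    OPERATIVE_VD = "OPERATIVE_VD"
    ICD_AFTER_FAILURE = "ICD_AFTER_FAILURE"
    ICD = "ICD"

    @property
    def binary(self) -> BinaryOutcome:
        if self in (DetailedOutcome.ICD, DetailedOutcome.ICD_AFTER_FAILURE):
            return BinaryOutcome.CESAREAN
        return BinaryOutcome.VAGINAL


class Provenance(enum.Enum):
    FIXTURE = "FIXTURE"
    SYNTHETIC = "SYNTHETIC"
    USER = "USER"


@dataclass(frozen=True)
class DeliveryOutcome:
    binary: BinaryOutcome
    detailed: Optional[DetailedOutcome] = None

    def __post_init__(self) -> None:
        if self.detailed is not None and self.detailed.binary is not self.binary:
            raise CohortValidationError(
                f"detailed outcome {self.detailed.value} inconsistent with binary {self.binary.value}"
            )


def parse_outcome(token: str) -> DeliveryOutcome:
    """Parse an outcome token: ICD / NO ICD / NOICD or a detailed label."""
    norm = token.strip().upper().replace(" ", "_")
    if norm in ("ICD",):
        # Table convention: "ICD" rows include cesareans after a failed
        # vaginal attempt, so it maps to the binary outcome only.
        return DeliveryOutcome(binary=BinaryOutcome.CESAREAN)
    if norm in ("NOICD", "NO_ICD"):
        return DeliveryOutcome(binary=BinaryOutcome.VAGINAL)
    try:
        detailed = DetailedOutcome(norm)
    except ValueError:
        raise CohortValidationError(f"unparseable outcome token {token!r}") from None
    return DeliveryOutcome(binary=detailed.binary, detailed=detailed)


def _parse_color(token: str, context: str) -> ColorCode:
    try:
        return ColorCode(str(token).strip().upper())
    except ValueError:
        raise CohortValidationError(f"{context}: unparseable color token {token!r}") from None


@dataclass
class CaseRecord:
    patient_id: str
    mla_deg: float
    colors: ColorPattern
    outcome: DeliveryOutcome
    recorded_class: Optional[int] = None
    recorded_predictions: Optional[dict[str, str]] = None
    raw_profile: Optional[GeometricProfile] = None
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def aida_class(self) -> int:
        """Class recomputed from the colors by the non-green counting rule."""
        return assign_aida_class(self.colors)

    @property
    def stratum(self) -> Stratum:
        return stratum_from_canonical(canonical_mla(self.mla_deg).value)

    @property
    def is_cesarean(self) -> bool:
        return self.outcome.binary is BinaryOutcome.CESAREAN


@dataclass
class Cohort:
    cases: list[CaseRecord]
    provenance: Provenance = Provenance.USER

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.cases)

    def subset(self, predicate) -> "Cohort":
        return Cohort([c for c in self.cases if predicate(c)], provenance=self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.cases:
            row: dict[str, object] = {
                "patient_id": rec.patient_id,
                "mla_deg": rec.mla_deg,
                "aida_class": rec.recorded_class if rec.recorded_class is not None else rec.aida_class,
                "delivery_outcome": "ICD" if rec.is_cesarean else "NOICD",
                "aida_mla": rec.colors.mla.value,
                "aida_aop": rec.colors.aop.value,
                "aida_spd": rec.colors.hsd.value,
                "aida_ad": rec.colors.ad.value,
            }
            if rec.recorded_predictions:
                for algo, col in PREDICTION_COLUMNS.items():
                    row[col] = rec.recorded_predictions[algo]
            if rec.raw_profile is not None:
                row["aop"] = rec.raw_profile.aop
                row["hsd"] = rec.raw_profile.hsd
                row["ad"] = rec.raw_profile.ad
            row.update(rec.extras)
            rows.append(row)
        return pd.DataFrame(rows)


def _record_from_row(row: pd.Series, idx: int, known_columns: set[str]) -> CaseRecord:
    where = f"row {idx}"
    colors = ColorPattern(
        aop=_parse_color(row["aida_aop"], where),
        hsd=_parse_color(row["aida_spd"], where),
        mla=_parse_color(row["aida_mla"], where),
        ad=_parse_color(row["aida_ad"], where),
    )
    try:
        mla_deg = float(row["mla_deg"])
    except (TypeError, ValueError):
        raise CohortValidationError(f"{where}: unparseable mla_deg {row['mla_deg']!r}") from None
    try:
        outcome = parse_outcome(str(row["delivery_outcome"]))
    except CohortValidationError as exc:
        raise CohortValidationError(f"{where}: {exc}") from None

    predictions = None
    if all(col in row.index and pd.notna(row[col]) for col in PREDICTION_COLUMNS.values()):
        predictions = {}
        for algo, col in PREDICTION_COLUMNS.items():
            tok = str(row[col]).strip().upper().replace(" ", "")
            if tok not in ("ICD", "NOICD"):
                raise CohortValidationError(f"{where}: unparseable prediction token {row[col]!r}")
            predictions[algo] = tok

    raw_profile = None
    if all(col in row.index and pd.notna(row[col]) for col in RAW_COLUMNS):
        raw_profile = GeometricProfile(
            aop=float(row["aop"]), hsd=float(row["hsd"]), mla=mla_deg, ad=float(row["ad"])
        )

    recorded_class = None
    if "aida_class" in row.index and pd.notna(row["aida_class"]):
        recorded_class = int(row["aida_class"])

    # unknown columns ride along as text so round trips are exact
    extras = {
        col: str(row[col])
        for col in row.index
        if col not in known_columns and pd.notna(row[col])
    }
    return CaseRecord(
        patient_id=str(row["patient_id"]),
        mla_deg=mla_deg,
        colors=colors,
        outcome=outcome,
        recorded_class=recorded_class,
        recorded_predictions=predictions,
        raw_profile=raw_profile,
        extras=extras,
    )


def cohort_from_dataframe(df: pd.DataFrame, provenance: Provenance = Provenance.USER) -> Cohort:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing mandatory column(s): {', '.join(missing)}")
    known = set(REQUIRED_COLUMNS) | set(PREDICTION_COLUMNS.values()) | set(RAW_COLUMNS) | {"aida_class"}
    cases = [_record_from_row(row, idx, known) for idx, row in df.iterrows()]
    seen: dict[str, int] = {}
    for idx, rec in enumerate(cases):
        if rec.patient_id in seen:
            raise CohortValidationError(
                f"row {idx}: duplicate patient_id {rec.patient_id!r} (first at row {seen[rec.patient_id]})"
            )
        seen[rec.patient_id] = idx
    return Cohort(cases, provenance=provenance)


def read_cohort(path: str | Path, provenance: Provenance = Provenance.USER) -> Cohort:
    """Read a cohort CSV; errors are row-addressed."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if df.empty:
        raise CohortValidationError(f"{path}: no case rows")
    return cohort_from_dataframe(df, provenance=provenance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.to_dataframe().to_csv(path, index=False)


def _packaged_bytes(filename: str, expected_sha256: str) -> bytes:
    data = resources.files("aida_dystocia.data").joinpath(filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha256:
        raise FixtureIntegrityError(
            f"packaged file {filename} is corrupted (sha256 {digest} != {expected_sha256})"
        )
    return data


def load_fixture() -> Cohort:
    """The packaged 66-case transverse-position study cohort."""
    import io as _io

    data = _packaged_bytes(FIXTURE_FILENAME, FIXTURE_SHA256)
    df = pd.read_csv(_io.BytesIO(data), dtype={"patient_id": str})
    return cohort_from_dataframe(df, provenance=Provenance.FIXTURE)


def load_outcome_totals() -> pd.DataFrame:
    """Published aggregate counts by (AIDA class, stratum, detailed outcome).

    The per-case detailed outcome was never published; only this
    cross-tabulation was, so it ships as a separate table.
    """
    import io as _io

    data = _packaged_bytes(OUTCOME_TOTALS_FILENAME, OUTCOME_TOTALS_SHA256)
    return pd.read_csv(_io.BytesIO(data))


def validate_cohort(cohort: Cohort) -> list[str]:
    """Invariant report (empty list = clean); never raises.

    Checks the midline angle range, patient-id uniqueness and, where a
    recorded class is present, agreement with the non-green counting rule.
    """
    report: list[str] = []
    seen: set[str] = set()
    for rec in cohort:
        tag = f"patient {rec.patient_id}"
        if rec.patient_id in seen:
            report.append(f"{tag}: duplicate patient_id")
        seen.add(rec.patient_id)
        if not (0.0 <= rec.mla_deg < 360.0):
            report.append(f"{tag}: mla_deg {rec.mla_deg} outside [0, 360)")
        if rec.recorded_class is not None and rec.recorded_class != rec.aida_class:
            report.append(
                f"{tag}: recorded class {rec.recorded_class} != {rec.aida_class} from colors"
            )
    return report
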