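"""Arithmetic of fetal occiput position.

The fetal occiput direction in the maternal pelvis is described two ways in
obstetric sonography: as a position on a 12-hour clock face (the ISUOG
convention, 12:00 = occiput anterior midline) or as a rotation angle in
degrees. This module converts between the two, classifies an angle into the
four ISUOG sectors (occiput anterior, posterior, left/right transverse),
folds left- and right-sided angles onto a single canonical midline-angle
(MLA) scale, and assigns the transverse stratum used for risk analysis:

* CLASSIC       canonical MLA in [75, 105]  (the textbook LOT/ROT band)
* NEAR          canonical MLA in [70, 75)
* TRANSITIONAL  canonical MLA in [60, 70)
* OTHER         everything else (anterior, posterior, oblique)

Angles are always degrees. One clock minute equals 0.5 degrees; angles
increase from 12:00 toward the maternal left, so 3:00 = 90 deg (LOT) and
9:00 = 270 deg (ROT).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

DEGREES_PER_HOUR = 30.0
DEGREES_PER_MINUTE = 0.5


class Side(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    MIDLINE = "MIDLINE"


class Sector(enum.Enum):
    """ISUOG clock-face sector of the occiput."""

    OA = "OA"
    OP = "OP"
    OT_LEFT = "OT_LEFT"
    OT_RIGHT = "OT_RIGHT"


class Stratum(enum.Enum):
    """Transverse-position stratum by canonical midline angle."""

    CLASSIC = "CLASSIC"
    NEAR = "NEAR"
    TRANSITIONAL = "TRANSITIONAL"
    OTHER = "OTHER"


#: Canonical-MLA band per transverse stratum, inclusive integer-degree ends.
STRATUM_BANDS: dict[Stratum, tuple[float, float]] = {
    Stratum.CLASSIC: (75.0, 105.0),
    Stratum.NEAR: (70.0, 74.0),
    Stratum.TRANSITIONAL: (60.0, 69.0),
}


@dataclass(frozen=True)
class ClockPosition:
    """Occiput position on the ISUOG clock face, e.g. 3:30."""

    hour: int
    minute: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.hour <= 12):
            raise ValueError(f"clock hour must be in 1..12, got {self.hour}")
        if not (0 <= self.minute <= 59):
            raise ValueError(f"clock minute must be in 0..59, got {self.minute}")

    def __str__(self) -> str:
        return f"{self.hour}:{self.minute:02d}"


@dataclass(frozen=True)
class CanonicalMla:
    """Midline angle folded onto [0, 180] with the side it came from."""

    value: float
    side: Side


def normalize_angle(theta: float) -> float:
    """Normalize an angle in degrees to [0, 360)."""
    theta = float(theta) % 360.0
    return 0.0 if theta == 360.0 else theta


def clock_to_degrees(pos: ClockPosition) -> float:
    """Rotation angle of a clock position; 12:00 maps to 0 degrees."""
    return normalize_angle((pos.hour % 12) * DEGREES_PER_HOUR + pos.minute * DEGREES_PER_MINUTE)


def degrees_to_clock(theta: float) -> ClockPosition:
    """Nearest minute-resolution clock position for an angle in [0, 360)."""
    theta = normalize_angle(theta)
    total_minutes = round(theta / DEGREES_PER_MINUTE) % 720
    hour = total_minutes // 60
    return ClockPosition(hour=12 if hour == 0 else int(hour), minute=int(total_minutes % 60))


def isuog_sector(theta: float) -> Sector:
    """ISUOG sector of a rotation angle.

    The transverse bands are closed: [75, 105] is left occiput transverse,
    [255, 285] right occiput transverse. (105, 255) is posterior and the
    remainder anterior.
    """
    theta = normalize_angle(theta)
    if 75.0 <= theta <= 105.0:
        return Sector.OT_LEFT
    if 255.0 <= theta <= 285.0:
        return Sector.OT_RIGHT
    if 105.0 < theta < 255.0:
        return Sector.OP
    return Sector.OA


def canonical_mla(theta: float) -> CanonicalMla:
    """Fold a rotation angle onto the canonical [0, 180] midline-angle scale.

    Left-sided angles (0, 180) keep their value; right-sided angles
    (180, 360) are mirrored as 360 - theta. 0 and 180 are midline.
    """
    theta = normalize_angle(theta)
    if theta == 0.0 or theta == 180.0:
        return CanonicalMla(value=theta, side=Side.MIDLINE)
    if theta < 180.0:
        return CanonicalMla(value=theta, side=Side.LEFT)
    return CanonicalMla(value=360.0 - theta, side=Side.RIGHT)


def stratum_from_canonical(value: float) -> Stratum:
    """Stratum for a canonical midline angle in [0, 180]."""
    if 75.0 <= value <= 105.0:
        return Stratum.CLASSIC
    if 70.0 <= value < 75.0:
        return Stratum.NEAR
    if 60.0 <= value < 70.0:
        return Stratum.TRANSITIONAL
    return Stratum.OTHER


def mla_stratum(theta: float) -> Stratum:
    """Transverse stratum of a rotation angle (right side via mirroring)."""
    return stratum_from_canonical(canonical_mla(theta).value)
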