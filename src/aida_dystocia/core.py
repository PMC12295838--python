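"""The AIDA classification proper.

Each of the four intrapartum-ultrasound geometric parameters — angle of
progression (AoP), head-symphysis distance (HSD, also written SPD),
midline angle (MLA) and asynclitism degree (AD) — is coded GREEN
(favorable for vaginal delivery), YELLOW (intermediate risk) or RED (high
risk for cesarean delivery) against per-parameter threshold bands. The
AIDA class of a case is the count of parameters coded anything other than
GREEN, giving an ordinal 0-4 scale: class 0 is all-green, class 4 has no
green parameter left.

Threshold bands are configuration, not constants: the canonical clinical
cut-offs are external to this package, so :func:`placeholder_thresholds`
ships a clearly marked non-canonical default and every classification
entry point accepts a user-supplied :class:`ThresholdConfig`.
"""

from __future__ import annotations

import configparser
import enum
from dataclasses import dataclass
from pathlib import Path

from .geometry import canonical_mla

PARAMETERS = ("aop", "hsd", "mla", "ad")


class ColorCode(enum.Enum):
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"

    @property
    def risk_rank(self) -> int:
        """0 for GREEN, 1 for YELLOW, 2 for RED."""
        return {"GREEN": 0, "YELLOW": 1, "RED": 2}[self.value]


@dataclass(frozen=True)
class ColorPattern:
    """The four parameter color codes of one case."""

    aop: ColorCode
    hsd: ColorCode
    mla: ColorCode
    ad: ColorCode

    def __iter__(self):
        return iter((self.aop, self.hsd, self.mla, self.ad))

    def as_dict(self) -> dict[str, ColorCode]:
        return {"aop": self.aop, "hsd": self.hsd, "mla": self.mla, "ad": self.ad}


@dataclass(frozen=True)
class GeometricProfile:
    """Raw values of the four parameters (degrees for AoP/MLA/AD, mm for HSD)."""

    aop: float
    hsd: float
    mla: float
    ad: float


@dataclass(frozen=True)
class ParameterBands:
    """Threshold bands for one parameter.

    ``breakpoints`` are one or two strictly increasing values splitting the
    domain into GREEN/RED or GREEN/YELLOW/RED bands. ``risk_increasing``
    says whether risk grows with the value (True: GREEN is the low band).
    A value exactly on a breakpoint takes the riskier of the two adjacent
    colors — conservative for a screening context.
    """

    domain: tuple[float, float]
    breakpoints: tuple[float, ...]
    risk_increasing: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"empty domain {self.domain}")
        if len(self.breakpoints) not in (1, 2):
            raise ValueError("need one or two breakpoints")
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError(f"breakpoints must be strictly increasing: {self.breakpoints}")
        if not all(lo < b < hi for b in self.breakpoints):
            raise ValueError(f"breakpoints {self.breakpoints} outside domain {self.domain}")

    @property
    def colors_low_to_high(self) -> tuple[ColorCode, ...]:
        """Band colors from the low end of the domain to the high end."""
        if len(self.breakpoints) == 2:
            ordered = (ColorCode.GREEN, ColorCode.YELLOW, ColorCode.RED)
        else:
            ordered = (ColorCode.GREEN, ColorCode.RED)
        return ordered if self.risk_increasing else ordered[::-1]

    def band_interval(self, color: ColorCode) -> tuple[float, float]:
        """Half-open-ish interval of the band carrying ``color``.

        Returned as (low, high) within the domain; raises KeyError if this
        parameter has no band of that color.
        """
        edges = (self.domain[0], *self.breakpoints, self.domain[1])
        for i, c in enumerate(self.colors_low_to_high):
            if c is color:
                return edges[i], edges[i + 1]
        raise KeyError(f"no {color.value} band for this parameter")


class ThresholdValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-parameter threshold bands for the four AIDA parameters."""

    aop: ParameterBands
    hsd: ParameterBands
    mla: ParameterBands
    ad: ParameterBands

    def bands_for(self, parameter: str) -> ParameterBands:
        if parameter not in PARAMETERS:
            raise KeyError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)

    @classmethod
    def from_file(cls, path: str | Path) -> "ThresholdConfig":
        """Read bands from a flat INI-style file, one section per parameter.

        Each section needs ``domain`` (two comma-separated numbers),
        ``breakpoints`` (one or two) and ``risk_increasing`` (true/false).
        """
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise ThresholdValidationError(f"cannot read threshold file {path}")
        bands = {}
        for name in PARAMETERS:
            if name not in parser:
                raise ThresholdValidationError(f"threshold file missing [{name}] section")
            sec = parser[name]
            try:
                domain = tuple(float(v) for v in sec["domain"].split(","))
                breakpoints = tuple(float(v) for v in sec["breakpoints"].split(","))
                risk_increasing = sec.getboolean("risk_increasing", fallback=True)
                bands[name] = ParameterBands(domain, breakpoints, risk_increasing)
            except (KeyError, ValueError) as exc:
                raise ThresholdValidationError(f"bad [{name}] section: {exc}") from exc
        return cls(**bands)

    def to_file(self, path: str | Path) -> None:
        parser = configparser.ConfigParser()
        for name in PARAMETERS:
            b = self.bands_for(name)
            parser[name] = {
                "domain": f"{b.domain[0]},{b.domain[1]}",
                "breakpoints": ",".join(str(v) for v in b.breakpoints),
                "risk_increasing": str(b.risk_increasing).lower(),
            }
        with open(path, "w") as fh:
            parser.write(fh)


def placeholder_thresholds() -> ThresholdConfig:
    """A synthetic, NON-canonical threshold set for simulation and demos.

    The clinically validated cut-offs behind the published color codes are
    not part of this package; these bands are merely plausible on each
    parameter's scale and oriented the right way round (larger AoP is
    favorable, larger HSD/MLA/AD unfavorable). Analyses of recorded color
    codes never touch them.
    """
    return ThresholdConfig(
        aop=ParameterBands(domain=(40.0, 200.0), breakpoints=(110.0, 120.0), risk_increasing=False),
        hsd=ParameterBands(domain=(0.0, 50.0), breakpoints=(13.0, 15.0), risk_increasing=True),
        mla=ParameterBands(domain=(0.0, 180.0), breakpoints=(45.0, 60.0), risk_increasing=True),
        ad=ParameterBands(domain=(0.0, 60.0), breakpoints=(8.0, 12.0), risk_increasing=True),
    )


def classify_parameter(x: float, bands: ParameterBands, name: str = "parameter") -> ColorCode:
    """Color code a raw value against one parameter's bands.

    Values exactly on a breakpoint take the riskier adjacent color.
    """
    import math

    if not math.isfinite(x):
        raise ThresholdValidationError(f"{name}: value {x} is not finite")
    lo, hi = bands.domain
    if not (lo <= x <= hi):
        raise ThresholdValidationError(f"{name}: value {x} outside configured domain [{lo}, {hi}]")
    colors = bands.colors_low_to_high
    # Walk the bands from the low end; ties go to the riskier neighbor.
    for i, bp in enumerate(bands.breakpoints):
        if x < bp:
            return colors[i]
        if x == bp:
            left, right = colors[i], colors[i + 1]
            return left if left.risk_rank >= right.risk_rank else right
    return colors[-1]


def assign_aida_class(pattern: ColorPattern) -> int:
    """AIDA class = number of parameters coded non-GREEN (0..4)."""
    return sum(1 for c in pattern if c is not ColorCode.GREEN)


def profile_to_class(profile: GeometricProfile, thresholds: ThresholdConfig) -> tuple[ColorPattern, int]:
    """Color code a raw geometric profile and derive its AIDA class.

    The MLA is folded onto the canonical [0, 180] scale first, so
    right-sided rotation angles classify like their left-sided mirrors.
    """
    pattern = ColorPattern(
        aop=classify_parameter(profile.aop, thresholds.aop, "aop"),
        hsd=classify_parameter(profile.hsd, thresholds.hsd, "hsd"),
        mla=classify_parameter(canonical_mla(profile.mla).value, thresholds.mla, "mla"),
        ad=classify_parameter(profile.ad, thresholds.ad, "ad"),
    )
    return pattern, assign_aida_class(pattern)
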