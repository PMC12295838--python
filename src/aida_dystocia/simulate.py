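"""Synthetic intrapartum cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
mixture of transverse strata (classic / near / transitional), per-stratum
color-pattern distributions over the four AIDA parameters, the non-green
counting rule linking pattern to class, and a class-conditional cesarean
probability that rises monotonically to certainty at class 4. Defaults
are fitted to the packaged study cohort, with the sparse class-0/1 cells
smoothed (a calibration choice, not observed data).

Raw AoP/HSD/AD values are drawn from a latent multivariate normal
(optionally correlated) and mapped by a Gaussian copula into the
threshold band of each parameter's assigned color, so raw values and
color codes can never contradict each other under the active
:class:`~aida_dystocia.core.ThresholdConfig`. The MLA color is treated
differently: in the source classification the MLA code is not a pure
function of the angle (the study cohort contains a 60-degree case coded
GREEN alongside 64-degree cases coded RED), so the generator samples the
MLA code as part of the per-stratum pattern and samples the angle
uniformly within the stratum band, left or right side with equal
probability (right-sided cases are emitted in ROT coordinates, e.g. a
canonical 76 appears as 284 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .cohort import BinaryOutcome, CaseRecord, Cohort, DeliveryOutcome, Provenance
from .core import (
    ColorCode,
    ColorPattern,
    GeometricProfile,
    ThresholdConfig,
    assign_aida_class,
    placeholder_thresholds,
)
from .geometry import STRATUM_BANDS, Stratum

PatternKey = tuple[str, str, str, str]  # (aop, hsd, mla, ad) color names

#: Class-conditional cesarean probabilities: study-cohort empirical rates
#: for classes 2-4, with the single-case class-0 and two-case class-1
#: cells smoothed to a monotone ramp (calibration, not observed data).
DEFAULT_CD_PROB = {0: 0.25, 1: 0.5, 2: 0.9, 3: 0.90625, 4: 1.0}

_OTHER_BAND = (0.0, 59.0)


class InfeasibleConfigError(ValueError):
    pass


@dataclass
class SyntheticCohortConfig:
    n: int
    stratum_weights: dict[Stratum, float]
    color_model: dict[Stratum, dict[PatternKey, float]]
    cd_prob: dict[int, float]
    seed: int = 0
    thresholds: ThresholdConfig = field(default_factory=placeholder_thresholds)
    latent_correlation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InfeasibleConfigError("n must be non-negative")
        total = sum(self.stratum_weights.values())
        if not np.isclose(total, 1.0):
            raise InfeasibleConfigError(f"stratum weights sum to {total}, not 1")
        if any(w < 0 for w in self.stratum_weights.values()):
            raise InfeasibleConfigError("stratum weights must be non-negative")
        for k in range(5):
            p = self.cd_prob.get(k)
            if p is None or not (0.0 <= p <= 1.0):
                raise InfeasibleConfigError(f"cd_prob[{k}] missing or outside [0, 1]")
        for stratum, weight in self.stratum_weights.items():
            if weight > 0:
                patterns = self.color_model.get(stratum)
                if not patterns:
                    raise InfeasibleConfigError(
                        f"stratum {stratum.value} has weight {weight} but no color patterns"
                    )
                psum = sum(patterns.values())
                if not np.isclose(psum, 1.0):
                    raise InfeasibleConfigError(
                        f"{stratum.value} pattern probabilities sum to {psum}, not 1"
                    )
        if self.latent_correlation is not None:
            corr = np.asarray(self.latent_correlation, dtype=float)
            if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
                raise InfeasibleConfigError("latent_correlation must be symmetric 4x4")
            if np.any(np.linalg.eigvalsh(corr) <= 0):
                raise InfeasibleConfigError("latent_correlation must be positive definite")


def _pattern_from_key(key: PatternKey) -> ColorPattern:
    return ColorPattern(*(ColorCode(name) for name in key))


def _pattern_key(pattern: ColorPattern) -> PatternKey:
    return (pattern.aop.value, pattern.hsd.value, pattern.mla.value, pattern.ad.value)


def _sample_categorical(rng: np.random.Generator, items: list, probs: list[float]):
    return items[rng.choice(len(items), p=np.asarray(probs) / np.sum(probs))]


def generate_cohort(cfg: SyntheticCohortConfig) -> Cohort:
    """Draw a fully reproducible synthetic cohort from the config.

    Every case carries a raw geometric profile consistent with its
    AoP/HSD/AD colors under ``cfg.thresholds``, plus its generating
    stratum and class in ``extras``.
    """
    rng = np.random.default_rng(cfg.seed)
    strata = [s for s in Stratum if cfg.stratum_weights.get(s, 0.0) > 0]
    weights = [cfg.stratum_weights[s] for s in strata]
    corr = (
        np.asarray(cfg.latent_correlation, dtype=float)
        if cfg.latent_correlation is not None
        else np.eye(4)
    )
    chol = np.linalg.cholesky(corr)

    cases: list[CaseRecord] = []
    for i in range(cfg.n):
        stratum = _sample_categorical(rng, strata, weights)
        model = cfg.color_model[stratum]
        keys = sorted(model)  # sorted for seed-stable iteration order
        key = _sample_categorical(rng, keys, [model[k] for k in keys])
        pattern = _pattern_from_key(key)
        aida_class = assign_aida_class(pattern)
        cesarean = bool(rng.random() < cfg.cd_prob[aida_class])

        lo, hi = STRATUM_BANDS.get(stratum, _OTHER_BAND)
        canonical = float(rng.integers(int(lo), int(hi) + 1))
        side_right = bool(rng.random() < 0.5)
        theta = (360.0 - canonical) % 360.0 if side_right and canonical > 0 else canonical

        # Gaussian copula: correlated latent normals -> uniforms -> color bands.
        z = chol @ rng.standard_normal(4)
        u = norm.cdf(z)
        raw = {}
        for j, name in enumerate(("aop", "hsd", "ad")):
            bands = cfg.thresholds.bands_for(name)
            color = getattr(pattern, name)
            b_lo, b_hi = bands.band_interval(color)
            raw[name] = b_lo + u[j] * (b_hi - b_lo)

        cases.append(
            CaseRecord(
                patient_id=f"S{i + 1:04d}",
                mla_deg=theta,
                colors=pattern,
                outcome=DeliveryOutcome(
                    binary=BinaryOutcome.CESAREAN if cesarean else BinaryOutcome.VAGINAL
                ),
                raw_profile=GeometricProfile(
                    aop=raw["aop"], hsd=raw["hsd"], mla=theta, ad=raw["ad"]
                ),
                extras={"gen_stratum": stratum.value, "gen_class": str(aida_class)},
            )
        )
    return Cohort(cases, provenance=Provenance.SYNTHETIC)


def fit_config_from_cohort(
    cohort: Cohort, n: Optional[int] = None, seed: int = 0
) -> SyntheticCohortConfig:
    """Empirical generator config: stratum weights, per-stratum pattern
    frequencies and class-conditional cesarean rates of a cohort.

    Classes unobserved in the cohort get a rate linearly interpolated
    between their nearest observed neighbors (ends clamp to the nearest
    observed rate).
    """
    if len(cohort) == 0:
        raise ValueError("cannot fit a generator config to an empty cohort")
    total = len(cohort)
    weights: dict[Stratum, float] = {}
    color_model: dict[Stratum, dict[PatternKey, float]] = {}
    class_n = {k: 0 for k in range(5)}
    class_ces = {k: 0 for k in range(5)}
    for rec in cohort:
        weights[rec.stratum] = weights.get(rec.stratum, 0.0) + 1.0 / total
        bucket = color_model.setdefault(rec.stratum, {})
        key = _pattern_key(rec.colors)
        bucket[key] = bucket.get(key, 0.0) + 1.0
        class_n[rec.aida_class] += 1
        class_ces[rec.aida_class] += int(rec.is_cesarean)
    for bucket in color_model.values():
        s = sum(bucket.values())
        for key in bucket:
            bucket[key] /= s

    observed = {k: class_ces[k] / class_n[k] for k in range(5) if class_n[k] > 0}
    if not observed:
        raise ValueError("cohort has no classifiable cases")
    cd_prob: dict[int, float] = {}
    known = sorted(observed)
    for k in range(5):
        if k in observed:
            cd_prob[k] = observed[k]
            continue
        lower = [j for j in known if j < k]
        upper = [j for j in known if j > k]
        if lower and upper:
            j0, j1 = lower[-1], upper[0]
            w = (k - j0) / (j1 - j0)
            cd_prob[k] = (1 - w) * observed[j0] + w * observed[j1]
        else:
            cd_prob[k] = observed[lower[-1]] if lower else observed[upper[0]]

    return SyntheticCohortConfig(
        n=n if n is not None else total,
        stratum_weights=weights,
        color_model=color_model,
        cd_prob=cd_prob,
        seed=seed,
    )


def default_config(n: int = 66, seed: int = 0) -> SyntheticCohortConfig:
    """Config fitted to the packaged study cohort with smoothed low classes.

    The fitted class-0 rate (one case) and class-1 rate (two cases) are
    replaced by the :data:`DEFAULT_CD_PROB` ramp; classes 2-4 keep their
    empirical rates.
    """
    from .cohort import load_fixture

    cfg = fit_config_from_cohort(load_fixture(), n=n, seed=seed)
    cfg.cd_prob = dict(DEFAULT_CD_PROB)
    return cfg
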