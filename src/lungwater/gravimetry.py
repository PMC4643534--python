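"""Gravimetric extravascular lung water (EVLW).

The post-mortem reference method: the lung is weighed, homogenized with
an equal mass of added water (inducing hemolysis), and aliquots of
blood, homogenate and centrifuged supernatant are dried to constant
mass. Water fractions f = (wet − dry)/wet then give

    total lung water  Q_t = f_hom · (M_lung + M_added) − M_added

and the residual (intravascular) blood retained in the lung is
estimated by hemoglobin dilution: Hb released into the homogenate water
is referred to whole-blood Hb concentration, with a (1 − hematocrit)
plasma/cell partition correction,

    M_blood,res = (Hb_sup / Hb_blood) · (1 − Hct) · (M_lung + M_added)
    Q_iv        = M_blood,res · f_blood
    EVLW        = Q_t − Q_iv.

The hemoglobin-dilution convention here is the classic gravimetric
scheme; published variants differ in detail, and the synthetic-cohort
generator uses this exact forward model, so round trips are exact.

All masses in grams, concentrations in g/dL, hematocrit as a fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Union

__all__ = [
    "GravimetrySample",
    "EVLWResult",
    "Normalization",
    "water_fraction",
    "compute_evlw",
    "evlw_index",
]


class Normalization(str, Enum):
    """Denominator used to turn EVLW (g) into an index (EVLWI)."""

    PER_100G_BODY = "per_100g_body"
    PER_G_DRY_LUNG = "per_g_dry_lung"
    WET_DRY_RATIO = "wet_dry_ratio"


@dataclass(frozen=True)
class GravimetrySample:
    """Raw wet/dry masses and blood measurements for one animal."""

    lung_wet_mass: float
    added_water_mass: float
    homogenate_wet_mass: float
    homogenate_dry_mass: float
    supernatant_wet_mass: float
    supernatant_dry_mass: float
    blood_wet_mass: float
    blood_dry_mass: float
    blood_hb: float  # g/dL
    supernatant_hb: float  # g/dL
    hematocrit: float  # fraction in [0, 1)
    body_mass: float  # g

    def __post_init__(self) -> None:
        pairs = [
            ("homogenate", self.homogenate_wet_mass, self.homogenate_dry_mass),
            ("supernatant", self.supernatant_wet_mass, self.supernatant_dry_mass),
            ("blood", self.blood_wet_mass, self.blood_dry_mass),
        ]
        for name, wet, dry in pairs:
            if wet < 0 or dry < 0:
                raise ValueError(f"{name} masses must be ≥ 0")
            if dry > wet:
                raise ValueError(f"{name} dry mass {dry} exceeds wet mass {wet}")
        if self.lung_wet_mass < 0 or self.added_water_mass < 0:
            raise ValueError("lung and added-water masses must be ≥ 0")
        if not (0 <= self.hematocrit < 1):
            raise ValueError(f"hematocrit must be in [0, 1), got {self.hematocrit}")
        if self.supernatant_hb < 0 or self.blood_hb < 0:
            raise ValueError("hemoglobin concentrations must be ≥ 0")
        if self.supernatant_hb > 0 and self.blood_hb == 0:
            raise ValueError(
                "blood_hb = 0 with supernatant_hb > 0: residual-blood ratio undefined"
            )


@dataclass(frozen=True)
class EVLWResult:
    f_hom: float
    f_sup: float
    f_blood: float
    total_lung_water: float  # g
    residual_blood_mass: float  # g
    intravascular_water: float  # g
    evlw: float  # g
    evlw_index: float
    wet_dry_ratio: float
    normalization: Normalization
    flags: tuple[str, ...] = ()


def water_fraction(wet_mass: float, dry_mass: float) -> float:
    """Fractional water content (wet − dry)/wet of a dried aliquot."""
    if wet_mass <= 0:
        raise ValueError(f"wet mass must be > 0, got {wet_mass}")
    if dry_mass < 0 or dry_mass > wet_mass:
        raise ValueError(
            f"dry mass must lie in [0, wet mass]; got dry={dry_mass}, wet={wet_mass}"
        )
    return (wet_mass - dry_mass) / wet_mass


def compute_evlw(
    sample: GravimetrySample,
    normalization: Union[Normalization, str] = Normalization.PER_100G_BODY,
    negative_tolerance: float = 0.0,
) -> EVLWResult:
    """Derive EVLW and its normalized index from one gravimetry sample.

    A computed EVLW below ``-negative_tolerance`` (possible with noisy
    measurements) is flagged in ``flags`` rather than clipped, so that
    downstream agreement statistics are not biased.
    """
    normalization = Normalization(normalization)
    f_hom = water_fraction(sample.homogenate_wet_mass, sample.homogenate_dry_mass)
    f_sup = water_fraction(sample.supernatant_wet_mass, sample.supernatant_dry_mass)
    f_blood = water_fraction(sample.blood_wet_mass, sample.blood_dry_mass)

    homogenate_total = sample.lung_wet_mass + sample.added_water_mass
    total_lung_water = f_hom * homogenate_total - sample.added_water_mass

    if sample.supernatant_hb == 0:
        residual_blood = 0.0
    else:
        residual_blood = (
            (sample.supernatant_hb / sample.blood_hb)
            * (1.0 - sample.hematocrit)
            * homogenate_total
        )
    intravascular_water = residual_blood * f_blood
    evlw = total_lung_water - intravascular_water

    flags: list[str] = []
    if evlw < -abs(negative_tolerance):
        flags.append("negative_evlw")

    lung_dry_mass = (1.0 - f_hom) * homogenate_total
    wet_dry_ratio = (
        sample.lung_wet_mass / lung_dry_mass if lung_dry_mass > 0 else float("inf")
    )

    index = evlw_index(evlw, sample, normalization)
    return EVLWResult(
        f_hom=f_hom,
        f_sup=f_sup,
        f_blood=f_blood,
        total_lung_water=total_lung_water,
        residual_blood_mass=residual_blood,
        intravascular_water=intravascular_water,
        evlw=evlw,
        evlw_index=index,
        wet_dry_ratio=wet_dry_ratio,
        normalization=normalization,
        flags=tuple(flags),
    )


def evlw_index(
    evlw: float,
    sample: GravimetrySample,
    normalization: Union[Normalization, str] = Normalization.PER_100G_BODY,
) -> float:
    """Normalize EVLW (g) by the configured denominator."""
    normalization = Normalization(normalization)
    if normalization is Normalization.PER_100G_BODY:
        if sample.body_mass <= 0:
            raise ValueError("body mass must be > 0 for per_100g_body normalization")
        return evlw / (sample.body_mass / 100.0)
    if normalization is Normalization.PER_G_DRY_LUNG:
        f_hom = water_fraction(sample.homogenate_wet_mass, sample.homogenate_dry_mass)
        lung_dry = (1.0 - f_hom) * (sample.lung_wet_mass + sample.added_water_mass)
        if lung_dry <= 0:
            raise ValueError("implied dry lung mass must be > 0")
        return evlw / lung_dry
    # wet/dry ratio passthrough: the index is the crude edema ratio itself
    f_hom = water_fraction(sample.homogenate_wet_mass, sample.homogenate_dry_mass)
    lung_dry = (1.0 - f_hom) * (sample.lung_wet_mass + sample.added_water_mass)
    if lung_dry <= 0:
        raise ValueError("implied dry lung mass must be > 0")
    return sample.lung_wet_mass / lung_dry
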