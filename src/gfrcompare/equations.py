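"""Deterministic renal physiology formulas.

Creatinine-based GFR estimating equations (IDMS-traceable CKD-EPI and
bedside Schwartz, both written for plasma creatinine in μmol/l), creatinine
unit conversion and Jaffé-to-IDMS standardization, Dubois body surface
area, indexing of a raw clearance to 1.73 m², and the UV/P clearance of an
exogenous filtration marker.

All operations are pure functions, accept scalars or numpy arrays, and
perform no file I/O.  Creatinine is handled internally in μmol/l; mg/dl is
accepted only at conversion boundaries (1 mg/dl = 88.4 μmol/l).

The CKD-EPI equation is piecewise in creatinine with sex-specific
breakpoints (61.88 μmol/l for women, 79.56 μmol/l for men, i.e. 0.7 and
0.9 mg/dl).  Both pieces coincide at the breakpoint, so the equation is
continuous; :func:`egfr_ckd_epi` evaluates it for any age >= 2 years even
though it is an adult equation — comparing its behaviour in children
against the pediatric Schwartz equation is precisely the point of this
package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UMOL_PER_MGDL",
    "Sex",
    "GFRSource",
    "CreatinineValue",
    "GFRValue",
    "ClearancePeriod",
    "convert_creatinine",
    "standardize_jaffe_creatinine",
    "egfr_ckd_epi",
    "egfr_schwartz",
    "body_surface_area_dubois",
    "normalize_to_bsa",
    "uvp_clearance",
]

logger = logging.getLogger(__name__)

#: conversion factor between creatinine units: 1 mg/dl = 88.4 μmol/l
UMOL_PER_MGDL = 88.4

# CKD-EPI coefficients, creatinine in μmol/l
_CKD_EPI_FEMALE_BREAKPOINT = 61.88
_CKD_EPI_MALE_BREAKPOINT = 79.56
_CKD_EPI_FEMALE_COEF = 144.0
_CKD_EPI_MALE_COEF = 141.0
_CKD_EPI_FEMALE_LOW_EXP = -0.329
_CKD_EPI_MALE_LOW_EXP = -0.411
_CKD_EPI_HIGH_EXP = -1.209
_CKD_EPI_AGE_BASE = 0.993
_CKD_EPI_BLACK_FACTOR = 1.159

#: bedside Schwartz coefficient for height in cm and creatinine in μmol/l
SCHWARTZ_K_UMOL = 36.5

# Jaffé -> IDMS-standardized creatinine linear calibration (μmol/l)
_JAFFE_SLOPE = 0.9395
_JAFFE_INTERCEPT = 4.6964

_DUBOIS_COEF = 0.007184
_DUBOIS_HEIGHT_EXP = 0.725
_DUBOIS_WEIGHT_EXP = 0.425

#: reference body surface area for clearance indexing, m²
REFERENCE_BSA = 1.73


class Sex(str, Enum):
    """Biological sex as used by the estimating equations."""

    FEMALE = "F"
    MALE = "M"


class GFRSource(str, Enum):
    """Provenance of a GFR value."""

    MEASURED = "measured"
    CKD_EPI = "ckd_epi"
    SCHWARTZ = "schwartz"


@dataclass(frozen=True)
class CreatinineValue:
    """A plasma creatinine concentration with an explicit unit."""

    value: float
    unit: str  # "umol_l" or "mg_dl"

    def __post_init__(self) -> None:
        if self.unit not in ("umol_l", "mg_dl"):
            raise ValueError(f"unknown creatinine unit: {self.unit!r}")
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError("creatinine value must be positive and finite")


@dataclass(frozen=True)
class GFRValue:
    """A GFR in ml/min/1.73 m² labeled with its provenance."""

    value: float
    source: GFRSource

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError("GFR must be positive and finite")


@dataclass(frozen=True)
class ClearancePeriod:
    """One urine-collection period of a renal clearance measurement.

    Concentrations of the filtration marker in urine and plasma share an
    arbitrary (but common) unit; urine flow is in ml/min.
    """

    urine_concentration: float
    urine_flow: float
    plasma_concentration: float

    def __post_init__(self) -> None:
        for name in ("urine_concentration", "urine_flow", "plasma_concentration"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")


def _positive(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be positive and finite")
    return arr


def _maybe_scalar(arr: np.ndarray, *inputs) -> float | np.ndarray:
    if all(np.ndim(v) == 0 for v in inputs):
        return float(arr)
    return arr


def _female_mask(sex) -> np.ndarray:
    """Normalize 'F'/'M' (str, Sex, or arrays thereof) to a boolean mask."""
    raw = np.asarray(sex)
    codes = np.char.upper(raw.astype(str))
    female = codes == "F"
    male = codes == "M"
    if not np.all(female | male):
        bad = np.unique(raw[~(female | male)]) if raw.ndim else raw
        raise ValueError(f"sex must be 'F' or 'M', got {bad!r}")
    return female


def convert_creatinine(c: CreatinineValue, target_unit: str) -> CreatinineValue:
    """Convert a creatinine concentration between μmol/l and mg/dl.

    The conversion factor is 88.4 μmol/l per mg/dl; a same-unit request
    returns the input unchanged.
    """
    if target_unit not in ("umol_l", "mg_dl"):
        raise ValueError(f"unknown creatinine unit: {target_unit!r}")
    if target_unit == c.unit:
        return c
    if c.unit == "umol_l":
        return CreatinineValue(c.value / UMOL_PER_MGDL, "mg_dl")
    return CreatinineValue(c.value * UMOL_PER_MGDL, "umol_l")


def standardize_jaffe_creatinine(pcr_jaffe):
    """Map compensated-Jaffé creatinine (μmol/l) onto the IDMS scale.

    Linear calibration ``0.9395 * PCr_Jaffe + 4.6964`` obtained by
    regression of the colorimetric assay against liquid chromatography
    mass spectrometry.  Applies to records flagged as measured with the
    Jaffé technique; enzymatic values are already IDMS-traceable.
    """
    p = _positive(pcr_jaffe, "pcr_jaffe")
    return _maybe_scalar(_JAFFE_SLOPE * p + _JAFFE_INTERCEPT, pcr_jaffe)


def egfr_ckd_epi(pcr_umol_l, age_years, sex, is_black=False):
    """CKD-EPI estimated GFR in ml/min/1.73 m² (creatinine in μmol/l).

    Piecewise in creatinine around the sex-specific breakpoint
    (61.88 μmol/l women / 79.56 μmol/l men), with coefficient 144 (women)
    or 141 (men), exponents −0.329/−0.411 below and −1.209 above the
    breakpoint, an age factor 0.993^age, and a 1.159 multiplier for Black
    patients.  Age enters as a real number of years (no flooring).

    The equation was developed in adults; it is evaluated as printed for
    any age >= 2 so that its pediatric behaviour can be compared against
    the Schwartz equation.
    """
    pcr = _positive(pcr_umol_l, "pcr_umol_l")
    age = _positive(age_years, "age_years")
    female = _female_mask(sex)
    pcr, age, female, black = np.broadcast_arrays(
        pcr, age, female, np.asarray(is_black, dtype=bool)
    )

    n_pediatric = int(np.count_nonzero(age < 18))
    if n_pediatric:
        logger.info(
            "egfr_ckd_epi applied to %d record(s) under 18 y; "
            "the equation is adult-derived and is evaluated as printed",
            n_pediatric,
        )

    breakpoint_ = np.where(female, _CKD_EPI_FEMALE_BREAKPOINT, _CKD_EPI_MALE_BREAKPOINT)
    coef = np.where(female, _CKD_EPI_FEMALE_COEF, _CKD_EPI_MALE_COEF)
    low_exp = np.where(female, _CKD_EPI_FEMALE_LOW_EXP, _CKD_EPI_MALE_LOW_EXP)
    exponent = np.where(pcr <= breakpoint_, low_exp, _CKD_EPI_HIGH_EXP)

    egfr = coef * (pcr / breakpoint_) ** exponent * _CKD_EPI_AGE_BASE ** age
    egfr = np.where(black, egfr * _CKD_EPI_BLACK_FACTOR, egfr)
    return _maybe_scalar(egfr, pcr_umol_l, age_years, np.asarray(sex))


def egfr_schwartz(pcr_umol_l, height_cm):
    """Bedside Schwartz estimated GFR: ``36.5 × height (cm) / PCr (μmol/l)``.

    A pediatric equation (the coefficient encodes the child height-to-
    muscle-mass relation); this package also evaluates it in adults using
    measured height, which is the comparison of interest.
    """
    pcr = _positive(pcr_umol_l, "pcr_umol_l")
    height = _positive(height_cm, "height_cm")
    return _maybe_scalar(SCHWARTZ_K_UMOL * height / pcr, pcr_umol_l, height_cm)


def body_surface_area_dubois(height_cm, weight_kg):
    """Dubois body surface area: ``0.007184 × height^0.725 × weight^0.425`` m²."""
    h = _positive(height_cm, "height_cm")
    w = _positive(weight_kg, "weight_kg")
    bsa = _DUBOIS_COEF * h ** _DUBOIS_HEIGHT_EXP * w ** _DUBOIS_WEIGHT_EXP
    return _maybe_scalar(bsa, height_cm, weight_kg)


def normalize_to_bsa(clearance_ml_min, bsa_m2):
    """Index a raw clearance (ml/min) to 1.73 m² body surface area."""
    c = _positive(clearance_ml_min, "clearance_ml_min")
    b = _positive(bsa_m2, "bsa_m2")
    return _maybe_scalar(c * REFERENCE_BSA / b, clearance_ml_min, bsa_m2)


def uvp_clearance(periods: Iterable[ClearancePeriod]) -> float:
    """Mean UV/P clearance over 1–4 urine-collection periods, ml/min.

    Per-period clearance is ``urine_concentration × urine_flow /
    plasma_concentration``; the measurement protocol averages three to
    four periods.
    """
    periods = list(periods)
    if not 1 <= len(periods) <= 4:
        raise ValueError("uvp_clearance expects between 1 and 4 periods")
    per_period = [
        p.urine_concentration * p.urine_flow / p.plasma_concentration for p in periods
    ]
    return float(np.mean(per_period))
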