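"""Synthetic cohort generator for the equation-comparison pipeline.

The study this pipeline targets (a renal function exploration unit
cohort, ages 3–90, mGFR 3–160 ml/min/1.73 m²) is not publicly deposited,
so the package ships a generator that reproduces its statistical
structure: the age-class and sex composition, sex-specific adult heights,
a child growth curve, the mGFR category mix per age class, and a
creatinine–GFR generative relationship with multiplicative noise.

The generative creatinine model is this module's own construction (it is
NOT taken from any equation): plasma creatinine is creatinine production
divided by clearance,

    PCr = k · M(age, sex, height) / trueGFR · exp(ε),   ε ~ N(0, cv²)

where M is a muscle-mass index proportional to height, with a childhood
factor ramping to the adult level across puberty (ages 12–18), a female
factor ramping from 1.0 to 0.72 over the same span (sex divergence of
lean mass at puberty), and a configurable decline per decade after age 40
(sarcopenia; default 5%/decade).  k is calibrated so that a 40-year-old,
170 cm male with true GFR 100 has PCr = 80 μmol/l.  Measured GFR adds
log-normal measurement noise with CV 3.5% (the between-run precision of
the clearance assay).

Determinism: every participant draws from its own RNG substream derived
from (seed, participant index), so the first k records of a cohort do not
change when n grows and cohorts are byte-identical across runs and
platforms for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparison import AGE_CLASSES, GFR_CATEGORIES

__all__ = [
    "REFERENCE_COMPOSITION",
    "CohortConfig",
    "ExclusionLog",
    "muscle_mass_index",
    "simulate_true_pcr",
    "simulate_mgfr_measurement",
    "generate_cohort",
    "apply_exclusions",
    "PCR_CALIBRATION_K",
]

#: Composition of the reference cohort the generator emulates: participant
#: counts by age class, measured-GFR category, sex, and albuminuria
#: category.  These counts anchor the generator defaults and the
#: descriptive-table arithmetic.
REFERENCE_COMPOSITION = {
    "n_total": 10610,
    "mgfr_category_counts": {"<60": 3987, "60-89": 3469, ">=90": 3154},
    "age_class_counts": {
        "2-12": 750, "13-17": 430, "18-40": 2326, "41-64": 5246, ">=65": 1858
    },
    # rows: age class, columns: (<60, 60-89, >=90)
    "age_class_by_category": {
        "2-12": (58, 151, 541),
        "13-17": (61, 113, 256),
        "18-40": (523, 731, 1072),
        "41-64": (2067, 1966, 1213),
        ">=65": (1278, 508, 72),
    },
    "female_count": 4944,
    "transplant_counts": {"<60": 958, "60-89": 508, ">=90": 84},
    "albuminuria_category_counts": {"normal": 5861, "increased": 2957, "high": 1793},
    "albuminuria_by_category": {
        "<60": (1380, 1448, 1159),
        "60-89": (2225, 856, 388),
        ">=90": (2255, 653, 246),
    },
}

# ages are sampled uniformly within these bounds; the youngest class is
# labeled 2-12 y but referrals start at age 3
_AGE_SAMPLING_BOUNDS = {
    "2-12": (3.0, 13.0),
    "13-17": (13.0, 18.0),
    "18-40": (18.0, 41.0),
    "41-64": (41.0, 65.0),
    ">=65": (65.0, 90.0),
}

# --- muscle-mass index shape parameters (generator's own model) ---------
CHILD_MUSCLE_FACTOR = 0.78  # children produce less creatinine per cm of height
FEMALE_ADULT_FACTOR = 0.72  # adult female lean mass per height vs male
_MATURITY_RAMP = (12.0, 18.0)  # puberty: child -> adult factors
MUSCLE_FLOOR = 0.60  # the age decline never goes below this
_ANCHOR = {"age": 40.0, "height": 170.0, "gfr": 100.0, "pcr": 80.0}
#: k of the generative creatinine model, calibrated on the male anchor
PCR_CALIBRATION_K = _ANCHOR["pcr"] * _ANCHOR["gfr"] / _ANCHOR["height"]

# log-sd of true GFR within each category, from the reference quartiles
_DEFAULT_GFR_LOG_SD = (0.384, 0.152, 0.139)

_TRUE_GFR_RANGE = (3.0, 200.0)


def _normalized(counts: Sequence[float]) -> tuple[float, ...]:
    total = float(sum(counts))
    return tuple(c / total for c in counts)


def _default_gfr_mix() -> dict[str, tuple[float, ...]]:
    return {
        cls: _normalized(row)
        for cls, row in REFERENCE_COMPOSITION["age_class_by_category"].items()
    }


@dataclass(frozen=True)
class CohortConfig:
    """All generator knobs; defaults emulate the reference cohort."""

    n: int = 10610
    age_class_mix: tuple[float, ...] = (0.070, 0.040, 0.220, 0.495, 0.175)
    female_fraction: float = 0.466
    gfr_category_mix_by_age_class: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_gfr_mix
    )
    mgfr_category_medians: tuple[float, ...] = (42.0, 74.0, 106.0)
    mgfr_category_log_sd: tuple[float, ...] = _DEFAULT_GFR_LOG_SD
    measurement_cv: float = 0.035  # between-run precision of the clearance assay
    creatinine_noise_cv: float = 0.15  # residual biological PCr variability
    muscle_decline_per_decade: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if len(self.age_class_mix) != len(AGE_CLASSES):
            raise ValueError(f"age_class_mix needs {len(AGE_CLASSES)} proportions")
        for name, mix in [("age_class_mix", self.age_class_mix)] + [
            (f"gfr mix for {cls}", self.gfr_category_mix_by_age_class[cls])
            for cls in AGE_CLASSES
        ]:
            if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        for name, cv in (
            ("measurement_cv", self.measurement_cv),
            ("creatinine_noise_cv", self.creatinine_noise_cv),
        ):
            if not 0.0 <= cv <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5]")
        if any(m <= 0 for m in self.mgfr_category_medians):
            raise ValueError("mGFR category medians must be positive")


def muscle_mass_index(age, sex, height_cm, decline_per_decade: float = 0.05):
    """Relative creatinine-production (muscle-mass) index.

    Proportional to height; multiplied by a maturity factor (0.78 in
    childhood, ramping to 1.0 between ages 12 and 18), a sex factor
    (female lean mass ramps from parity in childhood to 0.72 of the male
    level across the same span), and an aging factor declining by
    ``decline_per_decade`` per decade after age 40 (floored at 0.60).
    """
    age = np.asarray(age, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    if np.any(age <= 0) or np.any(height <= 0):
        raise ValueError("age and height must be positive")
    female = np.char.upper(np.asarray(sex).astype(str)) == "F"

    ramp = np.clip((age - _MATURITY_RAMP[0]) / (_MATURITY_RAMP[1] - _MATURITY_RAMP[0]), 0.0, 1.0)
    maturity = CHILD_MUSCLE_FACTOR + (1.0 - CHILD_MUSCLE_FACTOR) * ramp
    sex_factor = np.where(female, 1.0 - (1.0 - FEMALE_ADULT_FACTOR) * ramp, 1.0)
    aging = np.maximum(
        MUSCLE_FLOOR, 1.0 - decline_per_decade * np.maximum(age - 40.0, 0.0) / 10.0
    )
    out = height * maturity * sex_factor * aging
    return float(out) if out.ndim == 0 else out


def simulate_true_pcr(
    true_gfr,
    age,
    sex,
    height_cm,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    decline_per_decade: float = 0.05,
):
    """Generative plasma creatinine (μmol/l) given the hidden true GFR.

    ``PCr = k · M(age, sex, height) / trueGFR · exp(ε)`` with
    ε ~ N(0, noise_cv²).  With ``noise_cv=0`` the output is deterministic;
    doubling ``true_gfr`` at fixed covariates halves PCr by construction.
    """
    gfr = np.asarray(true_gfr, dtype=float)
    if np.any(gfr <= 0) or not np.all(np.isfinite(gfr)):
        raise ValueError("true_gfr must be positive and finite")
    m = muscle_mass_index(age, sex, height_cm, decline_per_decade)
    pcr = PCR_CALIBRATION_K * np.asarray(m) / gfr
    if noise_cv > 0.0:
        if rng is None:
            raise ValueError("an rng is required when noise_cv > 0")
        pcr = pcr * np.exp(rng.normal(0.0, noise_cv, size=np.shape(pcr)))
    return float(pcr) if np.ndim(pcr) == 0 else pcr


def simulate_mgfr_measurement(
    true_gfr,
    measurement_cv: float = 0.035,
    rng: np.random.Generator | None = None,
):
    """Measured GFR: true GFR with log-normal measurement noise.

    ``mGFR = trueGFR · exp(δ)``, δ ~ N(0, measurement_cv²) — the net
    effect of averaging three to four UV/P clearance periods with the
    assay's between-run imprecision.  ``measurement_cv=0`` returns the input.
    """
    gfr = np.asarray(true_gfr, dtype=float)
    if np.any(gfr <= 0) or not np.all(np.isfinite(gfr)):
        raise ValueError("true_gfr must be positive and finite")
    if measurement_cv > 0.0:
        if rng is None:
            raise ValueError("an rng is required when measurement_cv > 0")
        gfr = gfr * np.exp(rng.normal(0.0, measurement_cv, size=np.shape(gfr)))
    return float(gfr) if np.ndim(gfr) == 0 else gfr


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _choice(rng: np.random.Generator, probs: Sequence[float]) -> int:
    u = rng.random()
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if u < acc:
            return i
    return len(probs) - 1


_ALBUMINURIA_BOUNDS = {"normal": (0.2, 3.0), "increased": (3.0, 30.0), "high": (30.0, 200.0)}
_ALBUMINURIA_LABELS = ("normal", "increased", "high")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample a synthetic participant table.

    Per participant: age class → age (uniform within class bounds), sex,
    height (children: linear growth curve with a sex offset; adults:
    sex-specific Gaussians around 172/160 cm), weight via a plausible BMI,
    an mGFR category and a log-normal true GFR around the category median,
    then PCr from the generative creatinine model and mGFR from the
    measurement model.  Transplant status and albuminuria are sampled per
    mGFR category as descriptive fields only.

    The ``true_gfr`` column is generator-only ground truth; it is excluded
    from written cohorts by default and never used by the analysis path.
    """
    rows = []
    mixes = [config.gfr_category_mix_by_age_class[cls] for cls in AGE_CLASSES]
    transplant_p = {
        cat: REFERENCE_COMPOSITION["transplant_counts"][cat]
        / REFERENCE_COMPOSITION["mgfr_category_counts"][cat]
        for cat in GFR_CATEGORIES
    }
    albumin_p = {
        cat: _normalized(REFERENCE_COMPOSITION["albuminuria_by_category"][cat])
        for cat in GFR_CATEGORIES
    }
    for i in range(config.n):
        rng = _participant_rng(config.seed, i)
        cls_idx = _choice(rng, config.age_class_mix)
        cls = AGE_CLASSES[cls_idx]
        lo, hi = _AGE_SAMPLING_BOUNDS[cls]
        age = lo + (hi - lo) * rng.random()
        sex = "F" if rng.random() < config.female_fraction else "M"

        if age < 18.0:
            sex_offset = (3.0 if sex == "M" else -3.0) * age / 18.0
            height = 78.0 + 5.3 * age + sex_offset + rng.normal(0.0, 6.0)
            height = float(np.clip(height, 70.0, 200.0))
            bmi = float(np.clip(15.5 + 0.35 * age + rng.normal(0.0, 1.8), 12.0, 35.0))
        else:
            center = 172.0 if sex == "M" else 160.0
            height = float(np.clip(center + rng.normal(0.0, 7.0), 140.0, 200.0))
            bmi = float(np.clip(24.5 + rng.normal(0.0, 4.0), 16.0, 45.0))
        weight = bmi * (height / 100.0) ** 2

        cat_idx = _choice(rng, mixes[cls_idx])
        cat = GFR_CATEGORIES[cat_idx]
        true_gfr = float(
            np.clip(
                config.mgfr_category_medians[cat_idx]
                * math.exp(rng.normal(0.0, config.mgfr_category_log_sd[cat_idx])),
                *_TRUE_GFR_RANGE,
            )
        )
        pcr = simulate_true_pcr(
            true_gfr, age, sex, height,
            noise_cv=config.creatinine_noise_cv, rng=rng,
            decline_per_decade=config.muscle_decline_per_decade,
        )
        mgfr = simulate_mgfr_measurement(true_gfr, config.measurement_cv, rng=rng)

        transplant = int(rng.random() < transplant_p[cat])
        alb_cat = _ALBUMINURIA_LABELS[_choice(rng, albumin_p[cat])]
        alo, ahi = _ALBUMINURIA_BOUNDS[alb_cat]
        albuminuria = float(np.exp(rng.uniform(np.log(alo), np.log(ahi))))

        rows.append(
            {
                "participant_id": f"P{i:06d}",
                "age_years": age,
                "sex": sex,
                "height_cm": height,
                "weight_kg": weight,
                "pcr_umol_l": pcr,
                "mgfr_ml_min_173": mgfr,
                "is_black": 0,
                "transplant": transplant,
                "albuminuria_mg_mmol": albuminuria,
                "pcr_method": "enzymatic",
                "true_gfr": true_gfr,
            }
        )
    columns = [
        "participant_id", "age_years", "sex", "height_cm", "weight_kg",
        "pcr_umol_l", "mgfr_ml_min_173", "is_black", "transplant",
        "albuminuria_mg_mmol", "pcr_method", "true_gfr",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class ExclusionLog:
    """Per-rule exclusion counts (a record may trip several rules)."""

    n_input: int
    n_mgfr_above_limit: int
    n_age_out_of_range: int
    n_kept: int


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the analysis-range exclusions to a participant table.

    Removes records with measured GFR strictly above 160 ml/min/1.73 m²
    (a value of exactly 160 is retained) or with age outside [2, 90]
    years.  Returns the survivors and a per-rule exclusion log.
    """
    if records.empty:
        return records.copy(), ExclusionLog(0, 0, 0, 0)
    mgfr = pd.to_numeric(records["mgfr_ml_min_173"], errors="coerce")
    age = pd.to_numeric(records["age_years"], errors="coerce")
    high_mgfr = mgfr > 160.0
    bad_age = (age < 2.0) | (age > 90.0)
    keep = ~(high_mgfr | bad_age)
    log = ExclusionLog(
        n_input=len(records),
        n_mgfr_above_limit=int(high_mgfr.sum()),
        n_age_out_of_range=int(bad_age.sum()),
        n_kept=int(keep.sum()),
    )
    return records.loc[keep].reset_index(drop=True), log
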