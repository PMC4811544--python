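"""Participant CSV reading/writing and run configuration.

The single interchange format is a comma-separated, UTF-8, "."-decimal CSV
with a header.  Required columns::

    participant_id, age_years, sex (F/M), height_cm, weight_kg,
    pcr_umol_l, mgfr_ml_min_173

Optional columns: ``is_black`` (0/1), ``transplant`` (0/1),
``albuminuria_mg_mmol``, ``pcr_method`` ("jaffe" or "enzymatic").  Unknown
columns are preserved on read but ignored by the analysis.  Creatinine is
accepted only in μmol/l; sources in mg/dl should be converted with
:func:`gfrcompare.equations.convert_creatinine` (factor 88.4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import equations

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "RowError",
    "RunConfig",
    "read_participants",
    "write_participants",
    "standardize_jaffe_rows",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "participant_id",
    "age_years",
    "sex",
    "height_cm",
    "weight_kg",
    "pcr_umol_l",
    "mgfr_ml_min_173",
)
OPTIONAL_COLUMNS = ("is_black", "transplant", "albuminuria_mg_mmol", "pcr_method")

_POSITIVE_COLUMNS = ("age_years", "height_cm", "weight_kg", "pcr_umol_l", "mgfr_ml_min_173")


@dataclass(frozen=True)
class RowError:
    """One rejected CSV row: 1-based file line number and the reason."""

    line: int
    reason: str


@dataclass(frozen=True)
class RunConfig:
    """Reproducibility envelope of one pipeline run."""

    seed: int = 0
    bootstrap_b: int = 2000
    alpha: float = 0.05
    apply_jaffe_calibration: bool = False

    def __post_init__(self) -> None:
        if self.bootstrap_b < 1:
            raise ValueError("bootstrap_b must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def read_participants(path) -> tuple[pd.DataFrame, list[RowError]]:
    """Read and validate a participant CSV.

    Per-row validation failures (non-numeric, non-positive, or missing
    required values; invalid sex codes) reject the row and are returned as
    :class:`RowError` entries with file line numbers; the run continues
    with the valid rows.  Missing required columns, an unreadable file, or
    a file in which every row is invalid raise :class:`ValueError`.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype={"participant_id": str, "sex": str, "pcr_method": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {', '.join(missing)}")

    errors: list[RowError] = []
    ok = pd.Series(True, index=frame.index)

    def reject(mask: pd.Series, reason_fmt: str) -> None:
        for idx in frame.index[mask & ok]:
            errors.append(RowError(line=int(idx) + 2, reason=reason_fmt))  # +2: header, 1-based
        ok[mask] = False

    reject(frame["participant_id"].isna() | (frame["participant_id"].str.strip() == ""),
           "missing participant_id")
    sex_ok = frame["sex"].astype(str).str.upper().isin(["F", "M"])
    reject(~sex_ok, "sex must be F or M")
    for col in _POSITIVE_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        frame[col] = vals
        reject(~np.isfinite(vals) | (vals <= 0), f"{col} must be a positive number")
    if "albuminuria_mg_mmol" in frame.columns:
        acr = pd.to_numeric(frame["albuminuria_mg_mmol"], errors="coerce")
        frame["albuminuria_mg_mmol"] = acr
        reject(acr.notna() & (acr < 0), "albuminuria_mg_mmol must be >= 0")
    for col in ("is_black", "transplant"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce").fillna(0).astype(int)

    for err in errors:
        logger.warning("%s line %d rejected: %s", path.name, err.line, err.reason)
    kept = frame.loc[ok].reset_index(drop=True)
    kept["sex"] = kept["sex"].astype(str).str.upper()
    if kept.empty and len(frame):
        raise ValueError(f"all {len(frame)} data row(s) in {path} failed validation")
    return kept, errors


def write_participants(records: pd.DataFrame, path, include_truth: bool = False) -> None:
    """Write a participant table as the interchange CSV.

    The generator-only ``true_gfr`` column is dropped unless
    ``include_truth``.  Floats are written at full round-trip precision.
    """
    frame = records.copy()
    if not include_truth and "true_gfr" in frame.columns:
        frame = frame.drop(columns=["true_gfr"])
    frame.to_csv(path, index=False)


def standardize_jaffe_rows(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply the Jaffé→IDMS creatinine calibration where flagged.

    Rows with ``pcr_method == "jaffe"`` get their creatinine passed
    through the linear standardization; the method flag is then updated to
    ``"jaffe_standardized"``.  Returns the new frame and the number of
    rows calibrated.
    """
    if "pcr_method" not in records.columns:
        return records, 0
    frame = records.copy()
    mask = frame["pcr_method"].astype(str).str.lower() == "jaffe"
    n = int(mask.sum())
    if n:
        frame.loc[mask, "pcr_umol_l"] = equations.standardize_jaffe_creatinine(
            frame.loc[mask, "pcr_umol_l"].to_numpy(dtype=float)
        )
        frame.loc[mask, "pcr_method"] = "jaffe_standardized"
    return frame, n
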