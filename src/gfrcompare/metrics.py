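"""Agreement statistics for eGFR validation.

The analysis currency is the dimensionless ratio r = eGFR/mGFR.  Following
KDIGO-style validation practice:

* bias       — mean of r (1.0 = unbiased; the ratio, not the difference,
               is used so that heterogeneity is constant across the GFR
               range),
* precision  — interquartile range (IQR) of r,
* accuracy   — P10 and P30, the percentage of estimates within ±10% / ±30%
               of the measured value (boundary inclusive),

each with a 95% percentile-bootstrap confidence interval (2.5th and 97.5th
percentiles of the statistic over B = 2,000 with-replacement resamples by
default).

Quantiles everywhere (IQR and bootstrap percentiles) use linear
interpolation between order statistics: the q-quantile of n ordered values
sits at fractional index q·(n−1) (numpy's default).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BootstrapSpec",
    "PerformanceSummary",
    "egfr_mgfr_ratio",
    "bias_mean_ratio",
    "precision_iqr",
    "accuracy_within",
    "p10_accuracy",
    "p30_accuracy",
    "bootstrap_percentile_ci",
    "summarize_performance",
    "derive_seed",
]

#: number of with-replacement resamples for the percentile bootstrap
DEFAULT_BOOTSTRAP_B = 2000


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling plan for percentile-bootstrap confidence intervals."""

    b: int = DEFAULT_BOOTSTRAP_B
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("bootstrap resample count must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PerformanceSummary:
    """Bias, precision, and accuracy of one equation in one stratum."""

    bias: float
    bias_ci: tuple[float, float]
    iqr: float
    iqr_ci: tuple[float, float]
    p10: float
    p10_ci: tuple[float, float]
    p30: float
    p30_ci: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p10 <= self.p30 <= 100.0):
            raise ValueError("accuracy must satisfy 0 <= P10 <= P30 <= 100")
        if self.iqr < 0 or self.bias <= 0:
            raise ValueError("IQR must be >= 0 and bias > 0")
        for est, (lo, hi) in (
            (self.bias, self.bias_ci),
            (self.iqr, self.iqr_ci),
            (self.p10, self.p10_ci),
            (self.p30, self.p30_ci),
        ):
            if not lo <= est <= hi:
                raise ValueError("confidence interval must contain its estimate")


def _ratio_array(values, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"sample must contain at least {min_n} value(s)")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("ratios must be positive and finite")
    return arr


def egfr_mgfr_ratio(egfr, mgfr):
    """Ratio of estimated to measured GFR (both in ml/min/1.73 m²)."""
    e = np.asarray(egfr, dtype=float)
    m = np.asarray(mgfr, dtype=float)
    for name, v in (("egfr", e), ("mgfr", m)):
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError(f"{name} must be positive and finite")
    out = e / m
    return float(out) if np.ndim(egfr) == 0 and np.ndim(mgfr) == 0 else out


def bias_mean_ratio(values, axis=None):
    """Bias: arithmetic mean of the eGFR/mGFR ratios."""
    if axis is None:
        return float(np.mean(_ratio_array(values, min_n=1)))
    return np.mean(np.asarray(values, dtype=float), axis=axis)


def precision_iqr(values, axis=None):
    """Precision: interquartile range Q3 − Q1 of the ratios.

    Quantiles use linear interpolation at fractional index q·(n−1), so
    e.g. {1, 2, 3, 4} has Q1 = 1.75, Q3 = 3.25, IQR = 1.5.
    """
    if axis is None:
        arr = _ratio_array(values, min_n=2)
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        return float(q3 - q1)
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75], axis=axis)
    return q3 - q1


def accuracy_within(values, tolerance, axis=None):
    """Percentage of ratios within ``tolerance`` of 1 (|r − 1| <= tol).

    ``tolerance=0.10`` gives P10 and ``0.30`` gives P30.  The boundary is
    counted inside: a ratio of exactly 1.10 contributes to P10 (a 1e-12
    absolute guard absorbs the binary representation error of decimal
    tolerances, so 1.10 - 1.0 > 0.10 in floating point still counts).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if axis is None:
        arr = _ratio_array(values, min_n=1)
        return float(100.0 * np.mean(np.abs(arr - 1.0) - tolerance <= 1e-12))
    arr = np.asarray(values, dtype=float)
    return 100.0 * np.mean(np.abs(arr - 1.0) - tolerance <= 1e-12, axis=axis)


def p10_accuracy(values, axis=None):
    """P10: percentage of estimates within ±10% of the measured value."""
    return accuracy_within(values, 0.10, axis=axis)


def p30_accuracy(values, axis=None):
    """P30: percentage of estimates within ±30% of the measured value."""
    return accuracy_within(values, 0.30, axis=axis)


def bootstrap_percentile_ci(
    values,
    statistic: Callable,
    spec: BootstrapSpec = BootstrapSpec(),
    _chunk: int = 256,
) -> tuple[float, float]:
    """95% (or 1−alpha) percentile-bootstrap CI of an arbitrary statistic.

    Draws ``spec.b`` with-replacement resamples of the full sample size,
    evaluates ``statistic`` on each, and returns the alpha/2 and 1−alpha/2
    quantiles of the resampled statistics (same linear-interpolation
    quantile convention as :func:`precision_iqr`).  Deterministic for a
    fixed ``spec.seed``.

    ``statistic`` may optionally accept an ``axis`` keyword (as the
    statistics in this module do), in which case whole blocks of resamples
    are evaluated vectorized; otherwise it is called once per resample.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("bootstrap requires at least 2 observations")
    rng = np.random.default_rng(spec.seed)
    n = arr.size
    stats = np.empty(spec.b, dtype=float)
    pos = 0
    while pos < spec.b:
        block = min(_chunk, spec.b - pos)
        idx = rng.integers(0, n, size=(block, n))
        resamples = arr[idx]
        try:
            stats[pos : pos + block] = statistic(resamples, axis=1)
        except TypeError:
            stats[pos : pos + block] = [statistic(row) for row in resamples]
        pos += block
    lo, hi = np.quantile(stats, [spec.alpha / 2.0, 1.0 - spec.alpha / 2.0])
    return float(lo), float(hi)


def derive_seed(master_seed: int, *labels) -> int:
    """Derive a reproducible sub-seed from a master seed and string labels.

    Each (stratum, equation, statistic) combination gets its own bootstrap
    stream so that adding or removing one table cell never perturbs the
    others.  The result is a 31-bit integer.
    """
    tag = zlib.crc32("/".join(str(p) for p in labels).encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def summarize_performance(
    values,
    b: int = DEFAULT_BOOTSTRAP_B,
    alpha: float = 0.05,
    seed: int = 0,
) -> PerformanceSummary:
    """Full bias/IQR/P10/P30 summary of a ratio sample with bootstrap CIs.

    Each statistic is bootstrapped on its own seed derived from ``seed``
    and the statistic name.
    """
    arr = _ratio_array(values, min_n=2)
    point = {
        "bias": bias_mean_ratio(arr),
        "iqr": precision_iqr(arr),
        "p10": p10_accuracy(arr),
        "p30": p30_accuracy(arr),
    }
    stat_fns = {
        "bias": bias_mean_ratio,
        "iqr": precision_iqr,
        "p10": p10_accuracy,
        "p30": p30_accuracy,
    }
    cis = {}
    for name, fn in stat_fns.items():
        spec = BootstrapSpec(b=b, alpha=alpha, seed=derive_seed(seed, name))
        lo, hi = bootstrap_percentile_ci(arr, fn, spec)
        # a percentile CI can exclude the point estimate in extreme strata
        # (heavily discrete statistic, tiny n); widen it to include the
        # point so every reported interval brackets its estimate
        cis[name] = (min(lo, point[name]), max(hi, point[name]))
    return PerformanceSummary(
        bias=point["bias"],
        bias_ci=cis["bias"],
        iqr=point["iqr"],
        iqr_ci=cis["iqr"],
        p10=point["p10"],
        p10_ci=cis["p10"],
        p30=point["p30"],
        p30_ci=cis["p30"],
        n=arr.size,
    )
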