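"""Stratified paired comparison of two eGFR equations against measured GFR.

The cohort is cut into five elementary age classes (2–12, 13–17, 18–40,
41–64, ≥65 completed years) and three renal-function categories of
measured GFR (<60, 60–89, ≥90 ml/min/1.73 m²).  Every participant
contributes two eGFR/mGFR ratios — one per equation — giving a balanced
paired design which is analyzed with a linear mixed-effects model with a
participant random intercept:

    r_ij = μ + β·1[equation_ij = CKD-EPI] (+ age-class terms) + u_i + e_ij,
    u_i ~ N(0, σ_u²),  e_ij ~ N(0, σ²)

fit by maximum likelihood (ML, not REML, so that nested models can be
compared by a likelihood-ratio ANOVA).  The equation×age-class interaction
is tested by comparing the additive and interaction models with a
chi-square likelihood-ratio test.

Because the design is exactly two observations per participant, ML has a
fast exact form: the within-participant contrasts d_i = (r_i1 − r_i2)/√2
and the participant means m_i = (r_i1 + r_i2)/√2 are independent Gaussians
with variances σ² and τ² = σ² + 2σ_u²; the fitter alternates generalized
least squares for the fixed effects with the closed-form variance updates,
which is coordinate ascent on the exact log-likelihood.  On balanced
covariate-free data the equation effect reduces to the paired mean
difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import equations, metrics

__all__ = [
    "AGE_CLASSES",
    "AGE_STRATA",
    "GFR_CATEGORIES",
    "GFR_STRATA",
    "EQUATION_LABELS",
    "StratumKey",
    "assign_age_class",
    "assign_gfr_category",
    "assign_albuminuria_category",
    "build_paired_ratio_table",
    "ComparisonResult",
    "fit_random_intercept_model",
    "LikelihoodRatioResult",
    "anova_equation_age_interaction",
    "summarize_stratum",
    "Report",
    "build_report",
]

logger = logging.getLogger(__name__)

#: elementary age classes (completed years), a partition of [2, 90]
AGE_CLASSES = ("2-12", "13-17", "18-40", "41-64", ">=65")
#: reporting strata: elementary classes plus the aggregates used in tables
AGE_STRATA = ("all", "<18", "2-12", "13-17", "adults", "18-40", "41-64", ">=65")
#: renal-function categories of measured GFR, a partition of (0, 160]
GFR_CATEGORIES = ("<60", "60-89", ">=90")
GFR_STRATA = ("all", "<60", "60-89", ">=90")
EQUATION_LABELS = ("CKD-EPI", "Schwartz")

_AGE_CLASS_EDGES = (2, 13, 18, 41, 65, 91)  # on floor(age)
_AGE_AGGREGATES = {
    "all": AGE_CLASSES,
    "<18": ("2-12", "13-17"),
    "adults": ("18-40", "41-64", ">=65"),
}
_GFR_AGGREGATES = {"all": GFR_CATEGORIES}

#: mGFR above this value (ml/min/1.73 m²) is outside the analysis range
MGFR_UPPER_LIMIT = 160.0
AGE_RANGE = (2.0, 90.0)


class StratumKey(NamedTuple):
    """Addresses one cell of the stratified report tables."""

    age_class: str
    gfr_category: str


def expand_age_stratum(age_stratum: str) -> tuple[str, ...]:
    """Elementary age classes composing a reporting stratum."""
    if age_stratum in AGE_CLASSES:
        return (age_stratum,)
    try:
        return _AGE_AGGREGATES[age_stratum]
    except KeyError:
        raise ValueError(f"unknown age stratum: {age_stratum!r}") from None


def expand_gfr_stratum(gfr_stratum: str) -> tuple[str, ...]:
    """Elementary mGFR categories composing a reporting stratum."""
    if gfr_stratum in GFR_CATEGORIES:
        return (gfr_stratum,)
    try:
        return _GFR_AGGREGATES[gfr_stratum]
    except KeyError:
        raise ValueError(f"unknown mGFR stratum: {gfr_stratum!r}") from None


def _age_class_codes(age: np.ndarray) -> np.ndarray:
    """Vectorized age-class index on completed years (floor of age)."""
    floored = np.floor(age)
    return np.digitize(floored, _AGE_CLASS_EDGES[1:-1], right=False)


def assign_age_class(age: float) -> str:
    """Age class by completed years: floor(40.9) = 40 is still '18-40'."""
    if not np.isfinite(age) or not AGE_RANGE[0] <= age <= AGE_RANGE[1]:
        raise ValueError(f"age must be within [{AGE_RANGE[0]:g}, {AGE_RANGE[1]:g}] years")
    return AGE_CLASSES[int(_age_class_codes(np.asarray(float(age))))]


def assign_gfr_category(mgfr: float) -> str:
    """Renal-function category of a measured GFR in (0, 160]."""
    if not np.isfinite(mgfr) or not 0 < mgfr <= MGFR_UPPER_LIMIT:
        raise ValueError(f"mGFR must be in (0, {MGFR_UPPER_LIMIT:g}]")
    if mgfr < 60:
        return "<60"
    if mgfr < 90:
        return "60-89"
    return ">=90"


def assign_albuminuria_category(acr: float) -> str:
    """Albuminuria category of a urine albumin-to-creatinine ratio (mg/mmol).

    normal < 3; increased 3–30 (inclusive both ends); high > 30.
    """
    if not np.isfinite(acr) or acr < 0:
        raise ValueError("albuminuria ratio must be >= 0")
    if acr < 3:
        return "normal"
    if acr <= 30:
        return "increased"
    return "high"


_REQUIRED_COLUMNS = (
    "participant_id",
    "age_years",
    "sex",
    "height_cm",
    "weight_kg",
    "pcr_umol_l",
    "mgfr_ml_min_173",
)


def _analysis_validity_mask(records: pd.DataFrame) -> tuple[pd.Series, dict[str, int]]:
    """Rows usable for the paired analysis, with reasons for drops."""
    reasons: dict[str, int] = {}
    ok = pd.Series(True, index=records.index)

    def drop(mask: pd.Series, reason: str) -> None:
        bad = mask & ok
        if bad.any():
            reasons[reason] = int(bad.sum())
        ok[bad] = False

    for col in ("age_years", "height_cm", "pcr_umol_l", "mgfr_ml_min_173"):
        vals = pd.to_numeric(records[col], errors="coerce")
        drop(~np.isfinite(vals) | (vals <= 0), f"missing or non-positive {col}")
    drop(records["sex"].isna() | ~records["sex"].astype(str).str.upper().isin(["F", "M"]),
         "missing or invalid sex")
    age = pd.to_numeric(records["age_years"], errors="coerce")
    drop((age < AGE_RANGE[0]) | (age > AGE_RANGE[1]), "age outside analysis range")
    mgfr = pd.to_numeric(records["mgfr_ml_min_173"], errors="coerce")
    drop(mgfr > MGFR_UPPER_LIMIT, "mGFR above analysis range")
    return ok, reasons


def build_paired_ratio_table(records: pd.DataFrame) -> pd.DataFrame:
    """Long-format table with two rows (one per equation) per participant.

    Computes both eGFRs from the participant records, the eGFR/mGFR
    ratios, and the stratum labels.  Rows with missing or out-of-range
    required fields are skipped with a logged reason.

    Columns of the result: participant_id, equation, egfr, mgfr, ratio,
    age_class, gfr_category.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing required columns: {missing}")
    if records.empty:
        return pd.DataFrame(
            columns=["participant_id", "equation", "egfr", "mgfr", "ratio",
                     "age_class", "gfr_category"]
        )
    ok, reasons = _analysis_validity_mask(records)
    for reason, count in reasons.items():
        logger.warning("skipped %d record(s): %s", count, reason)
    kept = records.loc[ok]
    if kept.empty:
        return pd.DataFrame(
            columns=["participant_id", "equation", "egfr", "mgfr", "ratio",
                     "age_class", "gfr_category"]
        )

    age = kept["age_years"].to_numpy(dtype=float)
    sex = kept["sex"].astype(str).str.upper().to_numpy()
    height = kept["height_cm"].to_numpy(dtype=float)
    pcr = kept["pcr_umol_l"].to_numpy(dtype=float)
    mgfr = kept["mgfr_ml_min_173"].to_numpy(dtype=float)
    if "is_black" in kept.columns:
        black = kept["is_black"].fillna(0).astype(float).to_numpy() > 0
    else:
        black = np.zeros(len(kept), dtype=bool)

    egfr_ckd = np.asarray(equations.egfr_ckd_epi(pcr, age, sex, black))
    egfr_sch = np.asarray(equations.egfr_schwartz(pcr, height))
    age_class = np.asarray(AGE_CLASSES)[_age_class_codes(age)]
    gfr_cat = np.asarray(GFR_CATEGORIES)[np.digitize(mgfr, [60.0, 90.0])]

    n = len(kept)
    pid = kept["participant_id"].astype(str).to_numpy()
    table = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, 2),
            "equation": np.tile(EQUATION_LABELS, n),
            "egfr": np.ravel(np.column_stack([egfr_ckd, egfr_sch])),
            "mgfr": np.repeat(mgfr, 2),
            "age_class": np.repeat(age_class, 2),
            "gfr_category": np.repeat(gfr_cat, 2),
        }
    )
    table["ratio"] = metrics.egfr_mgfr_ratio(
        table["egfr"].to_numpy(), table["mgfr"].to_numpy()
    )
    return table


# ---------------------------------------------------------------------------
# exact ML for the balanced paired random-intercept model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """Mixed-model comparison of the two equations' mean ratios."""

    n_participants: int
    equation_effect: float  # mean ratio difference, CKD-EPI − Schwartz
    equation_effect_se: float
    dof: int  # t degrees of freedom for the Wald test (n_participants − 1)
    p_value: float
    mean_ratios: dict  # equation label -> (mean, (ci_low, ci_high))
    between_variance: float  # participant random-intercept variance σ_u²
    residual_variance: float  # within-participant residual variance σ²
    loglik: float
    n_fixed_params: int


class LikelihoodRatioResult(NamedTuple):
    """Nested-model ANOVA for the equation×age-class interaction."""

    statistic: float
    df: int
    p_value: float
    ll_full: float
    ll_reduced: float


class _PairedML(NamedTuple):
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float  # residual variance σ²
    tau2: float  # variance of participant means on the √2 scale, σ² + 2σ_u²
    loglik: float


def _fit_paired_ml(
    y1: np.ndarray, y2: np.ndarray, x1: np.ndarray, x2: np.ndarray,
    tol: float = 1e-13, max_iter: int = 1000,
) -> _PairedML:
    """Exact ML for two observations per subject with a random intercept.

    ``y1``/``x1`` and ``y2``/``x2`` are the per-subject responses and fixed-
    effect design rows for the two within-subject conditions.
    """
    n, p = x1.shape
    sqrt2 = math.sqrt(2.0)
    d = (y1 - y2) / sqrt2
    m = (y1 + y2) / sqrt2
    xd = (x1 - x2) / sqrt2
    xm = (x1 + x2) / sqrt2

    z = np.vstack([xd, xm])
    if np.linalg.matrix_rank(z) < p:
        raise ValueError("singular fixed-effects design")
    v = np.concatenate([d, m])

    scale = float(np.var(v)) or 1.0
    s2 = t2 = scale
    beta = np.zeros(p)
    for _ in range(max_iter):
        w = np.concatenate([np.full(n, 1.0 / s2), np.full(n, 1.0 / t2)])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(z * sw[:, None], v * sw, rcond=None)
        rd = d - xd @ beta
        rm = m - xm @ beta
        s2_new = max(float(rd @ rd) / n, 1e-300)
        t2_new = max(float(rm @ rm) / n, 1e-300)
        if t2_new < s2_new:
            # σ_u² would be negative: ML solution is on the boundary
            # σ_u² = 0, where both blocks share one pooled variance
            s2_new = t2_new = (float(rd @ rd) + float(rm @ rm)) / (2 * n)
        if (abs(s2_new - s2) <= tol * s2) and (abs(t2_new - t2) <= tol * t2):
            s2, t2 = s2_new, t2_new
            break
        s2, t2 = s2_new, t2_new

    rd = d - xd @ beta
    rm = m - xm @ beta
    ll = (
        -0.5 * n * math.log(2 * math.pi * s2) - float(rd @ rd) / (2 * s2)
        - 0.5 * n * math.log(2 * math.pi * t2) - float(rm @ rm) / (2 * t2)
    )
    info = xd.T @ xd / s2 + xm.T @ xm / t2
    cov_beta = np.linalg.inv(info)
    return _PairedML(beta=beta, cov_beta=cov_beta, sigma2=s2, tau2=t2, loglik=ll)


def _paired_arrays(table: pd.DataFrame):
    """Pivot the long table to per-participant paired arrays, validating pairing."""
    needed = {"participant_id", "equation", "ratio", "age_class"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"paired table is missing columns: {sorted(missing)}")
    counts = table.groupby(["participant_id", "equation"]).size()
    if (counts != 1).any():
        raise ValueError("each participant needs exactly one row per equation")
    wide = table.pivot(index="participant_id", columns="equation", values="ratio")
    if set(wide.columns) != set(EQUATION_LABELS) or wide.isna().any().any():
        raise ValueError("each participant needs both equations' ratios")
    wide = wide.sort_index()
    age = (
        table.drop_duplicates("participant_id")
        .set_index("participant_id")["age_class"]
        .reindex(wide.index)
    )
    return (
        wide[EQUATION_LABELS[0]].to_numpy(dtype=float),  # CKD-EPI
        wide[EQUATION_LABELS[1]].to_numpy(dtype=float),  # Schwartz
        age.to_numpy(),
    )


def _design(age_class: np.ndarray, equation_is_ckd: bool, with_interaction: bool,
            classes: Sequence[str]) -> np.ndarray:
    n = len(age_class)
    cols = [np.ones(n), np.full(n, 1.0 if equation_is_ckd else 0.0)]
    dummies = [(age_class == c).astype(float) for c in classes[1:]]
    cols.extend(dummies)
    if with_interaction:
        cols.extend([d * (1.0 if equation_is_ckd else 0.0) for d in dummies])
    return np.column_stack(cols)


def fit_random_intercept_model(
    table: pd.DataFrame,
    with_age_interaction: bool = False,
    include_age_class: bool | None = None,
) -> ComparisonResult:
    """Fit the random-intercept comparison of the two equations by ML.

    The fixed part is an intercept plus the equation indicator
    (1 = CKD-EPI, so the effect is the CKD-EPI − Schwartz mean-ratio
    difference); with ``include_age_class`` (implied by
    ``with_age_interaction``) age-class main effects, and optionally the
    equation×age-class interaction, are added.  The equation effect is
    tested with a Wald t-test on n_participants − 1 degrees of freedom.

    On balanced covariate-free data the effect estimate equals the paired
    mean difference exactly.
    """
    r_ckd, r_sch, age_class = _paired_arrays(table)
    n = len(r_ckd)
    if n < 2:
        raise ValueError("at least 2 participants are required")
    if include_age_class is None:
        include_age_class = with_age_interaction

    if np.ptp(np.concatenate([r_ckd, r_sch])) == 0.0:
        # all ratios identical: no information, both variances zero
        val = float(r_ckd[0])
        ci = (val, val)
        return ComparisonResult(
            n_participants=n, equation_effect=0.0, equation_effect_se=0.0,
            dof=n - 1, p_value=1.0,
            mean_ratios={lab: (val, ci) for lab in EQUATION_LABELS},
            between_variance=0.0, residual_variance=0.0,
            loglik=math.nan, n_fixed_params=2,
        )

    classes = [c for c in AGE_CLASSES if c in set(age_class)] if include_age_class else [None]
    if include_age_class:
        x1 = _design(age_class, True, with_age_interaction, classes)
        x2 = _design(age_class, False, with_age_interaction, classes)
    else:
        x1 = np.column_stack([np.ones(n), np.ones(n)])
        x2 = np.column_stack([np.ones(n), np.zeros(n)])

    fit = _fit_paired_ml(r_ckd, r_sch, x1, x2)
    effect = float(fit.beta[1])
    se = float(math.sqrt(max(fit.cov_beta[1, 1], 0.0)))
    dof = n - 1
    if se > 0:
        p = float(2.0 * sps.t.sf(abs(effect) / se, dof))
    else:
        p = 1.0 if effect == 0.0 else 0.0

    sigma_u2 = max((fit.tau2 - fit.sigma2) / 2.0, 0.0)
    total_var = sigma_u2 + fit.sigma2
    tcrit = float(sps.t.ppf(0.975, dof))
    mean_ratios = {}
    for lab, vals in zip(EQUATION_LABELS, (r_ckd, r_sch)):
        mu = float(np.mean(vals))
        half = tcrit * math.sqrt(total_var / n)
        mean_ratios[lab] = (mu, (mu - half, mu + half))

    return ComparisonResult(
        n_participants=n,
        equation_effect=effect,
        equation_effect_se=se,
        dof=dof,
        p_value=p,
        mean_ratios=mean_ratios,
        between_variance=sigma_u2,
        residual_variance=fit.sigma2,
        loglik=fit.loglik,
        n_fixed_params=x1.shape[1],
    )


def anova_equation_age_interaction(table: pd.DataFrame) -> LikelihoodRatioResult:
    """Likelihood-ratio ANOVA for the equation×age-class interaction.

    Fits the additive (equation + age class) and interaction models by ML
    on identical rows and compares them with a chi-square test on the
    difference in fixed-effect count.
    """
    reduced = fit_random_intercept_model(table, with_age_interaction=False,
                                         include_age_class=True)
    full = fit_random_intercept_model(table, with_age_interaction=True)
    df = full.n_fixed_params - reduced.n_fixed_params
    if df < 1:
        raise ValueError("only one age class present; interaction is not testable")
    stat = 2.0 * (full.loglik - reduced.loglik)
    stat = max(stat, 0.0)  # guard roundoff at the boundary
    p = float(sps.chi2.sf(stat, df))
    return LikelihoodRatioResult(
        statistic=float(stat), df=df, p_value=p,
        ll_full=full.loglik, ll_reduced=reduced.loglik,
    )


def _stratum_values(table: pd.DataFrame, stratum: StratumKey, equation: str) -> np.ndarray:
    if equation not in EQUATION_LABELS:
        raise ValueError(f"unknown equation label: {equation!r}")
    mask = (
        (table["equation"] == equation)
        & table["age_class"].isin(expand_age_stratum(stratum.age_class))
        & table["gfr_category"].isin(expand_gfr_stratum(stratum.gfr_category))
    )
    return table.loc[mask, "ratio"].to_numpy(dtype=float)


def summarize_stratum(
    table: pd.DataFrame,
    stratum: StratumKey,
    equation: str,
    b: int = metrics.DEFAULT_BOOTSTRAP_B,
    alpha: float = 0.05,
    seed: int = 0,
) -> metrics.PerformanceSummary | None:
    """Bias/IQR/P10/P30 with bootstrap CIs for one table cell.

    Returns ``None`` for an empty (or single-observation) stratum — the
    report renders these as explicit empty cells rather than dropping the
    row.  The bootstrap seed is derived from ``seed`` and the cell address
    so each cell has its own reproducible stream.
    """
    values = _stratum_values(table, stratum, equation)
    if values.size < 2:
        return None
    cell_seed = metrics.derive_seed(seed, stratum.age_class, stratum.gfr_category, equation)
    return metrics.summarize_performance(values, b=b, alpha=alpha, seed=cell_seed)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

_EMPTY_CELL = "NA"


def _fmt_est_ci(est: float, ci: tuple[float, float], nd: int) -> str:
    return f"{est:.{nd}f} ({ci[0]:.{nd}f}; {ci[1]:.{nd}f})"


def percent(count: int, total: int) -> float:
    """A percentage rounded to 1 decimal, as printed in cohort tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def _median_iqr(values: pd.Series, nd: int = 1) -> str:
    v = pd.to_numeric(values, errors="coerce").dropna()
    if v.empty:
        return _EMPTY_CELL
    q1, med, q3 = np.quantile(v.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    return f"{med:.{nd}f} [{q1:.{nd}f}; {q3:.{nd}f}]"


def _count_pct(count: int, total: int) -> str:
    return f"{count} ({percent(count, total):.1f}%)" if total else _EMPTY_CELL


@dataclass
class Report:
    """Stratified comparison report (descriptive, bias, accuracy, models)."""

    descriptive: pd.DataFrame
    bias_table: pd.DataFrame
    accuracy_children: pd.DataFrame
    accuracy_adults: pd.DataFrame
    model_table: pd.DataFrame
    summaries: dict
    metadata: dict

    def render_text(self) -> str:
        lines = ["Stratified eGFR equation comparison", "=" * 36, ""]
        for key in ("n_participants", "n_skipped", "master_seed", "bootstrap_b"):
            lines.append(f"{key}: {self.metadata[key]}")
        sections = [
            ("Cohort description", self.descriptive),
            ("Bias (mean eGFR/mGFR ratio) by stratum", self.bias_table),
            ("Precision and accuracy, children and adolescents", self.accuracy_children),
            ("Precision and accuracy, adults", self.accuracy_adults),
            ("Mixed-model comparison per mGFR category", self.model_table),
        ]
        for title, frame in sections:
            lines += ["", title, "-" * len(title), frame.to_string()]
        lines.append("")
        return "\n".join(lines)

    def write(self, outdir) -> list[Path]:
        """Write one CSV per table plus a plain-text rendering."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in (
            ("descriptive", self.descriptive),
            ("bias_by_stratum", self.bias_table),
            ("accuracy_children", self.accuracy_children),
            ("accuracy_adults", self.accuracy_adults),
            ("model_comparison", self.model_table),
        ):
            path = outdir / f"{name}.csv"
            frame.to_csv(path, float_format="%.6g")
            paths.append(path)
        text_path = outdir / "report.txt"
        text_path.write_text(self.render_text(), encoding="utf-8")
        paths.append(text_path)
        return paths


def _descriptive_table(records: pd.DataFrame, gfr_cat: np.ndarray) -> pd.DataFrame:
    cols = {"whole_sample": np.ones(len(records), dtype=bool)}
    for cat in GFR_CATEGORIES:
        cols[cat] = gfr_cat == cat
    age = records["age_years"].to_numpy(dtype=float)
    age_class = np.asarray(AGE_CLASSES)[_age_class_codes(age)]
    rows: dict[str, dict[str, str]] = {}
    for col_name, mask in cols.items():
        sub = records.loc[mask]
        total = len(sub)
        cell: dict[str, str] = {"participants": _count_pct(total, len(records))}
        for cls in AGE_CLASSES:
            cell[f"age class {cls} y"] = _count_pct(
                int(np.sum(mask & (age_class == cls))), total
            )
        cell["females"] = _count_pct(
            int((sub["sex"].astype(str).str.upper() == "F").sum()), total
        )
        if "transplant" in sub.columns:
            cell["kidney transplanted"] = _count_pct(
                int((pd.to_numeric(sub["transplant"], errors="coerce").fillna(0) > 0).sum()),
                total,
            )
        cell["age, years"] = _median_iqr(sub["age_years"])
        cell["height, cm"] = _median_iqr(sub["height_cm"])
        cell["weight, kg"] = _median_iqr(sub["weight_kg"])
        cell["PCr, umol/l"] = _median_iqr(sub["pcr_umol_l"], nd=0)
        cell["mGFR, ml/min/1.73m2"] = _median_iqr(sub["mgfr_ml_min_173"], nd=0)
        if "albuminuria_mg_mmol" in sub.columns:
            acr = pd.to_numeric(sub["albuminuria_mg_mmol"], errors="coerce").dropna()
            cell["albuminuria, mg/mmol"] = _median_iqr(acr, nd=2)
            n_acr = len(acr)
            cats = acr.map(assign_albuminuria_category)
            for label in ("normal", "increased", "high"):
                cell[f"albuminuria {label}"] = _count_pct(
                    int((cats == label).sum()), n_acr
                )
        rows[col_name] = cell
    frame = pd.DataFrame(rows)
    frame.index.name = "characteristic"
    return frame


def build_report(
    records: pd.DataFrame,
    master_seed: int,
    bootstrap_b: int = metrics.DEFAULT_BOOTSTRAP_B,
    alpha: float = 0.05,
) -> Report:
    """Assemble the full stratified comparison report.

    ``records`` is the participant table (exclusions should already have
    been applied; residual out-of-range rows are skipped and counted).
    Deterministic for fixed ``master_seed``: every bootstrap cell derives
    its own seed from it.

    Display rounding: ratios and IQR to 2 decimals, percentages to
    1 decimal; the underlying :class:`~gfrcompare.metrics.PerformanceSummary`
    objects in ``summaries`` keep full precision.
    """
    if records.empty:
        raise ValueError("cannot build a report from an empty cohort")
    table = build_paired_ratio_table(records)
    if table.empty:
        raise ValueError("no analyzable records after validation")
    ok, _ = _analysis_validity_mask(records)
    kept = records.loc[ok].reset_index(drop=True)
    n = len(kept)
    gfr_cat = np.asarray(GFR_CATEGORIES)[
        np.digitize(kept["mgfr_ml_min_173"].to_numpy(dtype=float), [60.0, 90.0])
    ]

    descriptive = _descriptive_table(kept, gfr_cat)

    summaries: dict[tuple[str, str, str], metrics.PerformanceSummary | None] = {}
    for age_stratum in AGE_STRATA:
        for gfr_stratum in GFR_STRATA:
            for eq in EQUATION_LABELS:
                summaries[(age_stratum, gfr_stratum, eq)] = summarize_stratum(
                    table, StratumKey(age_stratum, gfr_stratum), eq,
                    b=bootstrap_b, alpha=alpha, seed=master_seed,
                )

    def bias_cell(age_s: str, gfr_s: str, eq: str) -> str:
        s = summaries[(age_s, gfr_s, eq)]
        return _EMPTY_CELL if s is None else _fmt_est_ci(s.bias, s.bias_ci, 2)

    bias_rows = []
    for gfr_s in GFR_STRATA:
        for age_s in AGE_STRATA:
            bias_rows.append(
                {
                    "mGFR_category": gfr_s,
                    "age_stratum": age_s,
                    EQUATION_LABELS[0]: bias_cell(age_s, gfr_s, EQUATION_LABELS[0]),
                    EQUATION_LABELS[1]: bias_cell(age_s, gfr_s, EQUATION_LABELS[1]),
                }
            )
    bias_table = pd.DataFrame(bias_rows).set_index(["mGFR_category", "age_stratum"])

    def accuracy_frame(age_strata: Sequence[str]) -> pd.DataFrame:
        rows = []
        for gfr_s in GFR_STRATA:
            for stat_name, attr, ci_attr, nd in (
                ("IQR", "iqr", "iqr_ci", 2),
                ("P10", "p10", "p10_ci", 1),
                ("P30", "p30", "p30_ci", 1),
            ):
                row: dict[str, str] = {"mGFR_category": gfr_s, "index": stat_name}
                for age_s in age_strata:
                    for eq in EQUATION_LABELS:
                        s = summaries[(age_s, gfr_s, eq)]
                        cell = (
                            _EMPTY_CELL
                            if s is None
                            else _fmt_est_ci(getattr(s, attr), getattr(s, ci_attr), nd)
                        )
                        row[f"{age_s} | {eq}"] = cell
                rows.append(row)
        return pd.DataFrame(rows).set_index(["mGFR_category", "index"])

    accuracy_children = accuracy_frame(["<18", "2-12", "13-17"])
    accuracy_adults = accuracy_frame(["adults", "18-40", "41-64", ">=65"])

    model_rows = []
    for gfr_s in GFR_STRATA:
        sub = table[table["gfr_category"].isin(expand_gfr_stratum(gfr_s))]
        n_sub = sub["participant_id"].nunique()
        row: dict[str, object] = {"mGFR_category": gfr_s, "n": n_sub}
        if n_sub >= 2:
            fit = fit_random_intercept_model(sub)
            row.update(
                equation_effect=fit.equation_effect,
                effect_se=fit.equation_effect_se,
                effect_p=fit.p_value,
                mean_ratio_ckd_epi=fit.mean_ratios[EQUATION_LABELS[0]][0],
                mean_ratio_schwartz=fit.mean_ratios[EQUATION_LABELS[1]][0],
            )
            if sub["age_class"].nunique() >= 2:
                lrt = anova_equation_age_interaction(sub)
                row.update(
                    interaction_lr=lrt.statistic,
                    interaction_df=lrt.df,
                    interaction_p=lrt.p_value,
                )
        model_rows.append(row)
    model_table = pd.DataFrame(model_rows).set_index("mGFR_category")

    metadata = {
        "n_participants": n,
        "n_skipped": len(records) - n,
        "master_seed": int(master_seed),
        "bootstrap_b": int(bootstrap_b),
        "alpha": float(alpha),
    }
    return Report(
        descriptive=descriptive,
        bias_table=bias_table,
        accuracy_children=accuracy_children,
        accuracy_adults=accuracy_adults,
        model_table=model_table,
        summaries=summaries,
        metadata=metadata,
    )
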