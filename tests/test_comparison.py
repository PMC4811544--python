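"""Tests for stratification, the paired mixed model, and report assembly."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gfrcompare.cohort import CohortConfig, generate_cohort
from gfrcompare.comparison import (
    AGE_CLASSES,
    AGE_STRATA,
    EQUATION_LABELS,
    GFR_STRATA,
    StratumKey,
    assign_age_class,
    assign_albuminuria_category,
    assign_gfr_category,
    build_paired_ratio_table,
    build_report,
    expand_age_stratum,
    fit_random_intercept_model,
    percent,
    summarize_stratum,
    anova_equation_age_interaction,
)

from conftest import make_paired_table


class TestStratumAssignment:
    @pytest.mark.parametrize(
        "age, expected",
        [(2.0, "2-12"), (12.9, "2-12"), (13.0, "13-17"), (17.99, "13-17"),
         (18.0, "18-40"), (40.5, "18-40"), (41.0, "41-64"), (64.9, "41-64"),
         (65.0, ">=65"), (90.0, ">=65")],
    )
    def test_age_class_by_completed_years(self, age, expected):
        assert assign_age_class(age) == expected

    @pytest.mark.parametrize("age", [1.9, 90.1, float("nan")])
    def test_age_out_of_range(self, age):
        with pytest.raises(ValueError):
            assign_age_class(age)

    @pytest.mark.parametrize(
        "mgfr, expected",
        [(59.99, "<60"), (60.0, "60-89"), (89.99, "60-89"), (90.0, ">=90"),
         (106.0, ">=90"), (160.0, ">=90"), (3.0, "<60")],
    )
    def test_gfr_category(self, mgfr, expected):
        assert assign_gfr_category(mgfr) == expected

    @pytest.mark.parametrize("mgfr", [0.0, -5.0, 160.01])
    def test_gfr_out_of_range(self, mgfr):
        with pytest.raises(ValueError):
            assign_gfr_category(mgfr)

    @pytest.mark.parametrize(
        "acr, expected",
        [(2.21, "normal"), (2.99, "normal"), (3.0, "increased"), (6.92, "increased"),
         (30.0, "increased"), (30.01, "high"), (35.0, "high"), (0.0, "normal")],
    )
    def test_albuminuria_category(self, acr, expected):
        assert assign_albuminuria_category(acr) == expected

    def test_albuminuria_rejects_negative(self):
        with pytest.raises(ValueError):
            assign_albuminuria_category(-0.1)

    @given(age=st.floats(min_value=2.0, max_value=90.0))
    def test_age_classes_partition(self, age):
        cls = assign_age_class(age)
        memberships = [c for c in AGE_CLASSES if cls in expand_age_stratum(c)]
        assert memberships == [cls]
        # aggregates are consistent
        assert (cls in expand_age_stratum("<18")) == (math.floor(age) < 18)
        assert (cls in expand_age_stratum("adults")) == (math.floor(age) >= 18)


class TestPairedTable:
    def _one_record(self, **overrides):
        base = {
            "participant_id": "p1", "age_years": 10.0, "sex": "F",
            "height_cm": 100.0, "weight_kg": 30.0, "pcr_umol_l": 36.5,
            "mgfr_ml_min_173": 100.0,
        }
        base.update(overrides)
        return pd.DataFrame([base])

    def test_one_participant_two_rows(self):
        table = build_paired_ratio_table(self._one_record())
        assert len(table) == 2
        assert set(table["equation"]) == set(EQUATION_LABELS)

    def test_schwartz_ratio_exactly_one(self):
        # 36.5 × 100 / 36.5 = 100 = mGFR
        table = build_paired_ratio_table(self._one_record())
        schwartz = table.loc[table["equation"] == "Schwartz", "ratio"].iloc[0]
        assert schwartz == pytest.approx(1.0, rel=1e-12)

    def test_empty_input(self):
        table = build_paired_ratio_table(self._one_record().iloc[:0])
        assert table.empty

    def test_invalid_rows_skipped(self):
        records = pd.concat(
            [self._one_record(),
             self._one_record(participant_id="p2", pcr_umol_l=0.0),
             self._one_record(participant_id="p3", mgfr_ml_min_173=250.0)],
            ignore_index=True,
        )
        table = build_paired_ratio_table(records)
        assert set(table["participant_id"]) == {"p1"}

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="mgfr_ml_min_173"):
            build_paired_ratio_table(self._one_record().drop(columns=["mgfr_ml_min_173"]))


class TestRandomInterceptModel:
    def test_degenerate_all_identical(self):
        table = make_paired_table([1.1] * 5, [1.1] * 5)
        fit = fit_random_intercept_model(table)
        assert fit.equation_effect == 0.0
        assert fit.between_variance == 0.0 and fit.residual_variance == 0.0

    def test_two_participant_closed_form(self):
        table = make_paired_table([1.2, 1.4], [1.0, 1.2])
        fit = fit_random_intercept_model(table)
        assert fit.equation_effect == pytest.approx(0.2, abs=1e-12)
        assert fit.mean_ratios["CKD-EPI"][0] == pytest.approx(1.3)
        assert fit.mean_ratios["Schwartz"][0] == pytest.approx(1.1)

    def test_equals_paired_mean_difference(self):
        rng = np.random.default_rng(40)
        n = 150
        u = rng.normal(0, 0.2, n)
        r_ckd = 1.15 + u + rng.normal(0, 0.1, n)
        r_sch = 1.02 + u + rng.normal(0, 0.1, n)
        fit = fit_random_intercept_model(make_paired_table(r_ckd, r_sch))
        assert fit.equation_effect == pytest.approx(float(np.mean(r_ckd - r_sch)), abs=1e-8)

    def test_matches_statsmodels_ml(self):
        """Dual route: exact paired ML vs the general MixedLM optimizer."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(41)
        n = 200
        ages = np.asarray(AGE_CLASSES)[rng.integers(0, 5, n)]
        mu = pd.Series(ages).map(
            {"2-12": 1.5, "13-17": 1.3, "18-40": 1.1, "41-64": 1.0, ">=65": 0.95}
        ).to_numpy()
        u = rng.normal(0, 0.15, n)
        r_ckd = mu + 0.08 + u + rng.normal(0, 0.12, n)
        r_sch = mu + u + rng.normal(0, 0.12, n)
        table = make_paired_table(r_ckd, r_sch, age_class=ages)

        for with_int in (False, True):
            mine = fit_random_intercept_model(
                table, with_age_interaction=with_int, include_age_class=True
            )
            formula = (
                "ratio ~ C(equation, Treatment('Schwartz')) * C(age_class)"
                if with_int
                else "ratio ~ C(equation, Treatment('Schwartz')) + C(age_class)"
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = smf.mixedlm(
                    formula, table, groups=table["participant_id"]
                ).fit(reml=False)
            assert mine.loglik == pytest.approx(sm_fit.llf, abs=1e-6)
            if not with_int:
                eq_param = [p for p in sm_fit.fe_params.index if "equation" in p][0]
                assert mine.equation_effect == pytest.approx(
                    sm_fit.fe_params[eq_param], abs=1e-8
                )

    def test_unpaired_rows_rejected(self):
        table = make_paired_table([1.2, 1.4], [1.0, 1.2]).iloc[:-1]
        with pytest.raises(ValueError):
            fit_random_intercept_model(table)


class TestInteractionTest:
    def test_loglik_nesting(self):
        rng = np.random.default_rng(50)
        n = 120
        ages = np.asarray(AGE_CLASSES)[rng.integers(0, 5, n)]
        r_ckd = 1.1 + rng.normal(0, 0.15, n)
        r_sch = 1.0 + rng.normal(0, 0.15, n)
        result = anova_equation_age_interaction(make_paired_table(r_ckd, r_sch, age_class=ages))
        assert result.ll_full >= result.ll_reduced - 1e-8
        assert 0.0 <= result.p_value <= 1.0

    def test_detects_strong_interaction(self):
        # effect +0.3 in one class only: p < 0.001 virtually always
        for seed in range(5):
            rng = np.random.default_rng(60 + seed)
            n = 2000
            ages = np.asarray(AGE_CLASSES)[rng.integers(0, 5, n)]
            u = rng.normal(0, 0.15, n)
            boost = np.where(ages == "2-12", 0.3, 0.0)
            r_ckd = 1.05 + boost + u + rng.normal(0, 0.12, n)
            r_sch = 1.0 + u + rng.normal(0, 0.12, n)
            result = anova_equation_age_interaction(
                make_paired_table(r_ckd, r_sch, age_class=ages)
            )
            assert result.p_value < 1e-3

    def test_single_age_class_not_testable(self):
        table = make_paired_table([1.2, 1.4], [1.0, 1.2])
        with pytest.raises(ValueError):
            anova_equation_age_interaction(table)


class TestSummarizeStratum:
    def test_perfect_agreement_stratum(self):
        table = make_paired_table([1.0] * 6, [1.0] * 6)
        summary = summarize_stratum(table, StratumKey("18-40", "60-89"), "CKD-EPI",
                                    b=200, seed=1)
        assert summary.bias == pytest.approx(1.0)
        assert summary.iqr == 0.0
        assert summary.p10 == summary.p30 == 100.0

    def test_delegates_to_accuracy_metrics(self):
        table = make_paired_table([0.85, 0.95, 1.05, 1.35], [1.0] * 4)
        summary = summarize_stratum(table, StratumKey("all", "all"), "CKD-EPI",
                                    b=200, seed=1)
        assert summary.p10 == pytest.approx(50.0)
        assert summary.p30 == pytest.approx(75.0)
        assert summary.n == 4

    def test_empty_stratum_returns_marker(self):
        table = make_paired_table([1.1, 1.2], [1.0, 1.1], age_class="18-40")
        assert summarize_stratum(table, StratumKey("2-12", "all"), "CKD-EPI") is None


class TestPercent:
    def test_reference_cohort_rounding(self):
        assert percent(3987, 10610) == 37.6
        assert percent(3469, 10610) == 32.7
        assert percent(3154, 10610) == 29.7

    def test_rejects_empty_total(self):
        with pytest.raises(ValueError):
            percent(1, 0)


@pytest.fixture(scope="module")
def report():
    frame = generate_cohort(CohortConfig(n=900, seed=314))
    return frame, build_report(frame, master_seed=99, bootstrap_b=200)


class TestReport:

    def test_partition_conservation(self, report):
        _, rep = report
        for eq in EQUATION_LABELS:
            marginal = rep.summaries[("all", "all", eq)].n
            elementary = sum(
                rep.summaries[(cls, cat, eq)].n
                for cls in AGE_CLASSES
                for cat in ("<60", "60-89", ">=90")
                if rep.summaries[(cls, cat, eq)] is not None
            )
            # strata with fewer than 2 participants are rendered empty;
            # account for them via the bias table row count instead
            singles = marginal - elementary
            assert 0 <= singles <= len(AGE_CLASSES) * 3

    def test_marginal_counts_sum(self, report):
        _, rep = report
        for eq in EQUATION_LABELS:
            for cat in ("<60", "60-89", ">=90"):
                cells = [rep.summaries[(cls, cat, eq)] for cls in AGE_CLASSES]
                if all(c is not None for c in cells):
                    total = rep.summaries[("all", cat, eq)].n
                    assert total == sum(c.n for c in cells)

    def test_p30_at_least_p10_everywhere(self, report):
        _, rep = report
        for summary in rep.summaries.values():
            if summary is not None:
                assert summary.p30 >= summary.p10

    def test_deterministic_given_seed(self, report, tmp_path):
        frame, rep = report
        rep2 = build_report(frame, master_seed=99, bootstrap_b=200)
        assert rep.render_text() == rep2.render_text()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        paths1 = rep.write(d1)
        paths2 = rep2.write(d2)
        for p1, p2 in zip(paths1, paths2):
            assert p1.read_bytes() == p2.read_bytes()

    def test_all_strata_present(self, report):
        _, rep = report
        assert set(rep.bias_table.index) == {
            (g, a) for g in GFR_STRATA for a in AGE_STRATA
        }
        assert len(rep.accuracy_children.columns) == 3 * 2
        assert len(rep.accuracy_adults.columns) == 4 * 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_report(generate_cohort(CohortConfig(n=0)), master_seed=1)


def test_pediatric_report_recovers_generator_truth():
    """The <18 bias cells reproduce the generator-known pattern:
    Schwartz centered near 1, CKD-EPI strongly above 1."""
    frame = generate_cohort(CohortConfig(n=2500, seed=808))
    report = build_report(frame, master_seed=5, bootstrap_b=200)

    # independent truth: direct large-sample simulation, no report machinery
    big = generate_cohort(CohortConfig(n=12_000, seed=809))
    table = build_paired_ratio_table(big)
    young = table[table["age_class"].isin(["2-12", "13-17"])]
    for eq in EQUATION_LABELS:
        truth = young.loc[young["equation"] == eq, "ratio"]
        cell = report.summaries[("<18", "all", eq)]
        se = math.sqrt(
            truth.var(ddof=1) / cell.n + truth.var(ddof=1) / len(truth)
        )
        assert abs(cell.bias - truth.mean()) <= 3 * se
    assert report.summaries[("<18", "all", "CKD-EPI")].bias > 1.35
    assert abs(report.summaries[("<18", "all", "Schwartz")].bias - 1.0) < 0.1
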