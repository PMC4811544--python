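"""End-to-end stratified comparison of the two equations.

Simulates a cohort, fits the random-intercept model, tests the
equation×age-class interaction, and prints the bias table rows that carry
the study's central message.
"""

from gfrcompare import (
    CohortConfig,
    anova_equation_age_interaction,
    apply_exclusions,
    build_paired_ratio_table,
    build_report,
    fit_random_intercept_model,
    generate_cohort,
)

records = generate_cohort(CohortConfig(n=3000, seed=2024))
kept, log = apply_exclusions(records)
table = build_paired_ratio_table(kept)

fit = fit_random_intercept_model(table)
print(f"n = {fit.n_participants} participants, two ratios each")
for eq, (mean, ci) in fit.mean_ratios.items():
    print(f"  mean eGFR/mGFR ratio, {eq:9s}: {mean:.2f} ({ci[0]:.2f}; {ci[1]:.2f})")
print(f"  equation effect (CKD-EPI - Schwartz): {fit.equation_effect:.3f} "
      f"(SE {fit.equation_effect_se:.3f}, t-test p = {fit.p_value:.2g})")

lrt = anova_equation_age_interaction(table)
print(f"  equation x age-class interaction: LR = {lrt.statistic:.1f} "
      f"on {lrt.df} df, p = {lrt.p_value:.2g}")
print()

report = build_report(kept, master_seed=5, bootstrap_b=500)
print("bias (mean ratio) by age stratum, all mGFR levels:")
sub = report.bias_table.loc["all"]
print(sub.to_string())
print()
print("The equations trade places with age: the pediatric height-based")
print("equation is near 1 through young adulthood, while the adult")
print("equation overestimates in children and wins after 65 — hence the")
print("strongly significant interaction.")
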