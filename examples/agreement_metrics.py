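"""Bias, precision, and accuracy of one equation in one stratum.

Builds the paired eGFR/mGFR ratio table for a synthetic cohort and
summarizes the young-adult stratum with percentile-bootstrap confidence
intervals.
"""

from gfrcompare import (
    CohortConfig,
    StratumKey,
    apply_exclusions,
    build_paired_ratio_table,
    generate_cohort,
    summarize_stratum,
)

records, _ = apply_exclusions(generate_cohort(CohortConfig(n=3000, seed=7)))
table = build_paired_ratio_table(records)
stratum = StratumKey(age_class="18-40", gfr_category="all")

for equation in ("CKD-EPI", "Schwartz"):
    s = summarize_stratum(table, stratum, equation, b=2000, seed=123)
    print(f"{equation}, ages 18-40 (n={s.n})")
    print(f"  bias (mean eGFR/mGFR): {s.bias:.2f} ({s.bias_ci[0]:.2f}; {s.bias_ci[1]:.2f})")
    print(f"  precision (IQR):       {s.iqr:.2f} ({s.iqr_ci[0]:.2f}; {s.iqr_ci[1]:.2f})")
    print(f"  P10: {s.p10:5.1f} ({s.p10_ci[0]:.1f}; {s.p10_ci[1]:.1f})")
    print(f"  P30: {s.p30:5.1f} ({s.p30_ci[0]:.1f}; {s.p30_ci[1]:.1f})")
print()
print("A bias above 1 means the equation overestimates measured GFR on")
print("average; P30 is the share of estimates within +/-30% of the")
print("measurement (boundary included). CIs: 2.5th/97.5th percentiles of")
print("each statistic over 2,000 bootstrap resamples.")
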