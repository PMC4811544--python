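# gfrcompare

Agreement analysis of creatinine-based GFR estimating equations against
measured GFR, across the whole age range.

Clinical laboratories estimate kidney function from plasma creatinine
with age-group-specific equations: the CKD-EPI equation in adults and the
bedside Schwartz equation in children. The two are mathematically
unrelated — CKD-EPI uses a piecewise creatinine term with an age decay,
Schwartz is simply proportional to height/creatinine — so they disagree
at the pediatric–adult transition, and it is not obvious at what age a
laboratory should switch. `gfrcompare` implements the validation pipeline
that answers this question against a gold-standard measured GFR
(urinary inulin clearance): KDIGO-style agreement metrics, a paired
mixed-effects comparison, and stratified reporting by age class and
renal-function category, plus a synthetic cohort generator so the whole
pipeline is testable without patient data.

## The statistics

For each participant i and equation e, the analysis works on the ratio
r_ie = eGFR_ie / mGFR_i:

- **bias** — mean of r (1.0 = unbiased),
- **precision** — interquartile range of r,
- **accuracy** — P10 / P30, the percentage of estimates within ±10% /
  ±30% of the measurement,

each with a 95% percentile-bootstrap CI (2.5th/97.5th percentiles over
B = 2,000 resamples). The two equations are compared with a linear
mixed-effects model with participant random intercept,

    r_ie = μ + β·1[e = CKD-EPI] + u_i + ε_ie,

fit by maximum likelihood, with a Wald t-test for β and a
likelihood-ratio ANOVA of nested models for the equation×age-class
interaction. See `docs/methods.md` for conventions and derivations.

## Worked example

`examples/full_comparison.py` simulates a 3,000-participant cohort with
the default (reference-cohort-like) composition, fits the model, and
prints the bias table:

```
n = 2998 participants, two ratios each
  mean eGFR/mGFR ratio, CKD-EPI  : 1.07 (1.06; 1.08)
  mean eGFR/mGFR ratio, Schwartz : 0.99 (0.98; 1.00)
  equation effect (CKD-EPI - Schwartz): 0.079 (SE 0.005, t-test p = 2.1e-59)
  equation x age-class interaction: LR = 2920.4 on 4 df, p = 0

bias (mean ratio) by age stratum, all mGFR levels:
                       CKD-EPI           Schwartz
age_stratum
all          1.07 (1.06; 1.08)  0.99 (0.99; 1.00)
<18          1.55 (1.51; 1.59)  0.98 (0.96; 1.00)
2-12         1.68 (1.64; 1.72)  1.00 (0.98; 1.03)
13-17        1.26 (1.22; 1.31)  0.93 (0.90; 0.97)
adults       1.02 (1.01; 1.03)  0.99 (0.99; 1.00)
18-40        1.11 (1.10; 1.13)  0.92 (0.91; 0.94)
41-64        0.99 (0.98; 1.00)  0.98 (0.97; 0.99)
>=65         0.97 (0.95; 0.98)  1.14 (1.11; 1.16)
```

Reading it: a mean ratio of 1.55 means the adult equation overestimates
measured GFR by 55% on average in under-18s (its age term encodes adult
muscle-mass decline, not growth), while the height-based pediatric
equation stays near 1 through young adulthood and only breaks down after
65, where sarcopenia makes height a poor muscle-mass surrogate. The
strongly significant interaction says the equations' biases move in
opposite directions with age.

The other examples cover single-patient equation use
(`equations_tour.py`), the generator (`simulate_cohort.py`), and
stratum-level metrics (`agreement_metrics.py`). A thin CLI wraps the same
pipeline for shell use:

```sh
gfrcompare simulate --n 1000 --seed 7 --out runs/sim
gfrcompare compare --input runs/sim/cohort.csv --bootstrap-b 2000 --seed 7 --out runs/cmp
```

`compare` writes one CSV per report table (descriptive, bias by stratum,
accuracy for children and adults, model comparison), a plain-text
rendering, and a run log with the seed and exclusion counts. All outputs
are byte-reproducible from (input, seed).

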