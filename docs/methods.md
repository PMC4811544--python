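# Methods

## Problem and scope

`gfrcompare` implements an agreement analysis between two creatinine-based
GFR estimating equations — the adult CKD-EPI equation and the pediatric
bedside Schwartz equation — and a measured (inulin-clearance) GFR, across
age classes and renal-function categories. The package covers the whole
pipeline: the deterministic physiology formulas, a synthetic cohort
generator, the agreement statistics with bootstrap confidence intervals,
and the stratified mixed-model comparison with an interaction test.

## Equations and measurement formulas

Creatinine is handled in μmol/l throughout (1 mg/dl = 88.4 μmol/l; mg/dl
is accepted only at conversion boundaries).

**CKD-EPI** (creatinine in μmol/l, sex-specific breakpoint κ = 61.88 for
women / 79.56 for men, i.e. 0.7 / 0.9 mg/dl):

    eGFR = C · (PCr/κ)^a · 0.993^age · (1.159 if Black)

with C = 144 (women) / 141 (men), a = −0.329 (women) or −0.411 (men) for
PCr ≤ κ and a = −1.209 above it. Both pieces coincide at the breakpoint,
so the ≤ in the branch condition is observationally irrelevant (asserted
by a continuity test). Age enters as a real number of years, not floored:
the exponential form is continuous and no rounding convention is
specified for it; this is a documented choice and the only place the
package could disagree with an integer-age implementation (by at most a
factor 0.993 ≈ 0.7%).

The equation is adult-derived but is evaluated as printed for any age
≥ 2 — comparing its pediatric behaviour against Schwartz is the point of
the analysis — with only a logged notice for under-18 input.

**Bedside Schwartz**: eGFR = 36.5 · height(cm) / PCr(μmol/l), evaluated at
all ages using measured height.

**Supporting formulas**: Dubois body surface area
0.007184 · h^0.725 · w^0.425; clearance indexing by × 1.73/BSA; UV/P
clearance as the mean of 1–4 collection-period clearances
U·V/P; and the Jaffé-to-IDMS linear standardization
0.9395 · PCr + 4.6964 (μmol/l), which is exposed but applied only to rows
explicitly flagged `pcr_method = jaffe`, since enzymatic values are
already IDMS-traceable.

No rounding is applied in computation; display rounding (ratios and IQR
to 2 decimals, percentages to 1) happens only in report rendering.

## Agreement statistics

All statistics operate on the dimensionless ratio r = eGFR/mGFR. The
ratio rather than the difference is used because the between-individual
spread of eGFR − mGFR grows with GFR, while the ratio's heterogeneity is
roughly constant.

- **Bias**: mean of r (1 = unbiased).
- **Precision**: interquartile range of r.
- **Accuracy**: P10 and P30, the percentage of ratios with |r − 1| ≤ 0.10
  or 0.30. The boundary is counted inside ("within ±10%" read
  inclusively); a 1e-12 absolute guard absorbs the binary representation
  error of decimal tolerances so that a ratio of exactly 1.10 counts.
- **Confidence intervals**: percentile bootstrap — the 2.5th and 97.5th
  percentiles of the statistic over B = 2,000 with-replacement resamples
  (B configurable). Every table cell derives its own 31-bit seed from the
  master seed and the (stratum, equation, statistic) label via CRC-32 and
  `numpy.random.SeedSequence`, so cells are independently reproducible
  and adding a cell never perturbs the others. Intervals are widened, if
  necessary, to include the point estimate, so every reported interval
  brackets its estimate even in tiny, heavily discrete strata.

**Quantile convention.** All quantiles (IQR, bootstrap percentiles,
descriptive medians/IQRs) use linear interpolation between order
statistics — the q-quantile of n ordered values sits at fractional index
q·(n−1), numpy's default. Applied uniformly; e.g. the IQR of {1,2,3,4} is
3.25 − 1.75 = 1.5.

## Stratification

Five elementary age classes on completed years (floor of age): 2–12,
13–17, 18–40, 41–64, ≥65 — so age 40.9 is still "18–40". Aggregates <18,
adults (≥18), and "all" are reported alongside. Measured GFR is cut at
60 and 90 ml/min/1.73 m² into three categories partitioning (0, 160];
values above 160 (strictly) and ages outside [2, 90] are excluded
upstream with per-rule counts. Albuminuria categories: <3 mg/mmol normal,
3–30 inclusive increased, >30 high (descriptive only; feeds no
computation).

Empty report cells render as an explicit `NA` marker rather than being
dropped, keeping the table shape stable across cohorts.

## The paired mixed model

Each participant contributes both equations' ratios, giving a balanced
two-observations-per-subject design modeled as

    r_ij = μ + β·1[CKD-EPI] (+ age-class main effects and, optionally,
           equation×age-class interaction) + u_i + e_ij

with u_i ~ N(0, σ_u²) and e_ij ~ N(0, σ²), fit by **maximum likelihood**
(not REML) so that nested models are comparable by a likelihood-ratio
ANOVA. The interaction is tested by 2·(llₓ − ll₀) against χ² with df =
the added fixed-effect count.

For this design ML is computed exactly by an orthogonal decomposition:
within-pair contrasts d_i = (r_i1 − r_i2)/√2 ~ N(x_d'β, σ²) and pair
means m_i = (r_i1 + r_i2)/√2 ~ N(x_m'β, τ²), τ² = σ² + 2σ_u², are
independent, and the fitter alternates generalized least squares for β
with the closed-form variance updates (coordinate ascent on the exact
log-likelihood; relative tolerance 1e-13). When the update would give
σ_u² < 0 the solution is taken on the boundary σ_u² = 0 with a pooled
variance. The test suite verifies agreement with `statsmodels` MixedLM
(ML) to ~1e-6 in log-likelihood and ~1e-8 in the fixed effects; the
specialized fitter is used in production because it is exact for this
design and roughly three orders of magnitude faster, which makes the
500-replicate calibration study of the interaction test routine.

The equation effect β (CKD-EPI − Schwartz mean-ratio difference) is
tested with a Wald t-test on n_participants − 1 degrees of freedom — the
paired-design value; no Satterthwaite/Kenward-Roger correction is
applied. On balanced covariate-free data β equals the paired mean
difference exactly, and the Wald test is the paired t-test with the ML
(divide-by-n) variance. Per-equation mean ratios are reported with
t-intervals using the model's total variance (σ_u² + σ²)/n.

A fully degenerate input (all ratios identical) returns a zero effect,
zero variance components, p = 1, and an undefined (NaN) log-likelihood
rather than an error.

No multiple-testing adjustment is applied; p < 0.05 is nominal.

## Synthetic cohort generator

The generator is the package's own construction; its defaults encode the
composition of the reference cohort (n = 10,610) the analysis design
targets: age-class mix 7.0/4.0/22.0/49.5/17.5%, female fraction 46.6%,
per-age-class mGFR category mixes taken from the reference
class-by-category counts, category medians 42/74/106 ml/min/1.73 m², and
log-normal within-category spread matched to the printed quartiles
(log-SD 0.384/0.152/0.139).

Sampling per participant: age uniform within its class (from 3 years in
the 2–12 class, matching the referral floor; the class label keeps its
printed name), sex Bernoulli, height from a linear growth curve with a
sex offset in children and sex-specific Gaussians (172/160 cm, SD 7) in
adults, weight through a plausible BMI, a hidden true GFR, then:

- **Creatinine**: PCr = k · M(age, sex, height)/trueGFR · exp(ε),
  ε ~ N(0, cv²) with cv = 0.15 by default (residual biological
  variability of creatinine production; chosen to give ratio IQRs in the
  0.2–0.4 range typical of such validation cohorts). M is proportional
  to height with a childhood factor 0.78 ramping linearly to 1.0 over
  ages 12–18, a female factor ramping from 1.0 to 0.72 over the same
  span (sex divergence of lean mass at puberty), and a decline of
  5%/decade after age 40 (sarcopenia), floored at 0.60. k is calibrated
  so a 40-year-old, 170 cm male with true GFR 100 has PCr = 80 μmol/l.
  The childhood factor makes k·M/height ≈ 36.6 ≈ the Schwartz
  coefficient in children — which is exactly why that equation was
  derived with k = 36.5 there — and the post-40 decline is what lets the
  age-term-bearing adult equation win in the elderly.
- **Measured GFR**: mGFR = trueGFR · exp(δ), δ ~ N(0, 0.035²), the
  between-run precision of the clearance assay (the net effect of
  averaging 3–4 collection periods).

Log-normal noise is used throughout because the analysis currency is a
ratio: multiplicative errors keep all quantities positive and make
expectations analytic (a pseudo-equation with multiplicative bias b has
expected mean ratio b·exp((cv_ε² + cv_δ²)/2), which the recovery tests
exploit).

Transplant status and albuminuria are sampled from the reference
per-category proportions as descriptive fields only. Pediatric BMI
z-scores against national growth charts are not implemented; the
generator's internal height/BMI curves are a simplified stand-in and all
anthropometry beyond height is descriptive.

**What the generator does not emulate**: referral-driven selection,
within-person repeated measurements, transplant-specific physiology,
disease progression, non-white subpopulations (is_black defaults to 0,
as the reference cohort had few non-white participants), assay drift
between creatinine methods, and any correlation between albuminuria and
the creatinine residual. Passing end-to-end tests therefore demonstrates
that the *pipeline* recovers known generative truth — not that either
equation has any particular real-world accuracy.

**Determinism**: each participant draws from
`SeedSequence([seed, index])`, so cohorts are byte-identical across runs
and platforms for a fixed seed and the first k records never change when
n grows.

## Numerical and design choices

- Exclusion rule boundaries: mGFR exactly 160 is retained (the rule is
  strictly ">160"); category boundary values go to the upper label
  (mGFR 60.0 → "60–89", floor(age) 13 → "13–17").
- The bias CIs in the stratum tables are percentile-bootstrap like the
  IQR/P10/P30 CIs; the model-based mean-ratio CIs appear in the
  model-comparison table. Both are computed and labeled because either
  could back a published table.
- The LRT statistic is clipped at 0 to guard the rare case where the two
  fits' convergence roundoff would make it infinitesimally negative.
- Validation failures at I/O are collected per row (with file line
  numbers) and the run continues; only structural problems (missing
  columns, all rows invalid) are hard errors.

## Problem sizes in the shipped tests

The test suite runs the oracle comparisons at 1,000 random inputs, the
exhaustive bootstrap check at B = 50,000 against the 27-resample
enumeration, parameter recovery at n = 2,000, the interaction-test
type-I-error study at 500 replicates of n = 500 participants, and report
determinism at n = 400 with B = 200 — sizes at which every check is
stable under its stated tolerance while the whole suite stays fast. The
acceptance script regenerates its synthetic cohort at the full reference
scale (n = 10,610) with B = 2,000.

## Known limitations

- The Wald t degrees of freedom are exact only for the covariate-free
  paired design; with age-class terms they are a (conservative enough)
  approximation.
- The exact ML fitter requires complete pairs; participants with only
  one equation's ratio are rejected rather than handled by general
  missing-data machinery.
- The interaction ANOVA relies on the χ² asymptotics of the LRT; the
  shipped calibration study verifies the 5% level at n = 500 but very
  small cohorts should interpret the p-value cautiously.
- Only the single-marker bedside Schwartz and creatinine CKD-EPI
  equations are implemented; MDRD, multi-marker Schwartz, and
  cystatin-C equations are out of scope.
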