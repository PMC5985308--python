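# Methods

`wshort` evaluates abbreviated intelligence-test batteries: given a
battery's inter-subtest correlation matrix and reliabilities, it builds
every candidate 2- and 4-subtest short form from a verbal and a
performance pool, scores the forms on a simulated (or observed)
population, and summarises each form's fitness as a screening instrument
for intellectual giftedness.

## Score metrics and linear equating

Subtests are reported as scaled scores (mean 10, SD 3); composites live
on the deviation-IQ metric (mean 100, SD 15).  A short form is scored by
linearly equating the *sum* of its p scaled scores.  Because the sum of
correlated standardised subtests has standard deviation
`scaled_sd * sqrt(p + 2 * sum_{j<k} r_jk)`, the equating line

    IQ_SF = slope * (sum of scaled scores) + intercept
    slope = 15 / (3 * sqrt(p + 2*Σr_jk)),  intercept = 100 − slope * 10p

maps the population mean of the sum to 100 and its SD to 15.  The
unrounded coefficients are the computational path throughout; printed
2-decimal coefficients exist only as regression fixtures, and a
reporting option reproduces rounded-coefficient scoring for cross-checks
against published formulas.  Full composites (a 10-subtest FSIQ, a
6-subtest GAI) are equated the same way, parameterised by the composite
size m rather than a hard-coded 10, so every validity index can be
computed against either reference scale.  When an input file already
carries FSIQ/GAI columns (from norm tables), those are used verbatim and
the equated versions are kept alongside under distinct names.

## Population simulation

Populations are drawn multivariate normal via the lower Cholesky factor
of the battery correlation matrix, rescaled to the scaled-score metric.
The default simulation size is n = 1,000,000; the test suite uses
100,000–200,000 for most distributional checks and 1,000,000 where a
0.005 recovery bound is asserted.  Continuous scores are the default; an
optional discretisation rounds half-away-from-zero and clips to the
published range [1, 19], attenuating correlations by < 0.02 at these
sample sizes (asserted in tests).  Every run is reproducible from a
single integer seed, and pipeline manifests record seed, n, and a hash
of the battery config.

## Reliability indices

- **Composite reliability** `r_cc = (Σr_jj + 2Σr_jk) / (p + 2Σr_jk)` —
  analytic, from the battery's reliabilities and correlations.
- **SEM** `= 15 * sqrt(1 − r_cc)`, the classical-test-theory form.
- **Hierarchical omega** `ω_H = (Σ λ_g)² / (p + 2Σr_jk)`: the share of a
  form's sum-score variance carried by the battery's general factor.
  Because a general factor is not identifiable from 2 items, λ_g come
  from the *full* battery: an independent-cluster higher-order model
  (group factors = index membership, one second-order factor) is fitted
  to the correlation matrix by unweighted least squares — chosen over ML
  for robustness on hand-transcribed matrices — and collapsed by the
  Schmid–Leiman transformation (λ_g,i = λ_i γ_m).  Heywood loadings are
  clipped to [0, 1] with a warning; user-supplied loadings bypass the
  fit.  The optimiser starts from the square root of each row's mean
  absolute off-diagonal correlation, which avoids the λ = 0 saddle point
  of an identity matrix.
- **ICC(A,1)**: two-way random-effects, absolute-agreement,
  single-measure intraclass correlation from the two-way ANOVA mean
  squares; negative estimates are returned unfloored, and a zero-variance
  input yields NaN with a warning.

## Validity indices

- **Corrected correlation.**  A form shares measurement error with the
  full scale it is part of, inflating the raw Pearson r_sf.  The
  correction subtracts the shared-error term:
  `r′ = r_sf − (1 − r_cc) · sqrt(p + 2Σr_jk)/sqrt(m + 2Σr_lm) · SD_sf/15`.
  A strategy switch drops the `SD_sf/15` factor; the two variants
  coincide on equated simulated data where SD_sf = 15.  `r′ ≤ r_sf`
  always, with equality only at r_cc = 1.
- **Discrepancy.**  Two-tailed paired t-test of (form − full scale) with
  the correlation-adjusted repeated-measures effect size
  `d_rm = mean_diff / sqrt(sd1² + sd2² − 2 r sd1 sd2) · sqrt(2(1−r))`.
  A zero-variance difference is flagged rather than reported as an
  infinite t.  An optional Bonferroni flag scales the significance
  threshold across the evaluated family of forms.
- **Identification accuracy C_acc.**  Among cases truly at/above the
  cutoff on the full scale, the share whose short-form score is also
  at/above the cutoff *and* within ±2 SEM of the full-scale score.  The
  conditioning set (truly gifted on the full scale) is a design choice:
  the stability rule and the cutoff are standard, but the denominator is
  not fully pinned down by the usual verbal definitions; this reading
  matches the quantity's purpose — accuracy of gifted identification.
- **Agreement score R_c**: the unweighted mean of the eight panel values
  (r_cc, ω_H, and r′/ICC/C_acc against each of the two reference
  scales).  This 8-value reading reproduces, within rounding, every
  published agreement score in the regression fixtures.  Forms are
  ranked by descending R_c within size class; ties break by r_cc, then
  name.

## Screening evaluation

Classification at the cutoff (default 125, the 95th percentile) counts
ties as positive.  AUC is the Mann–Whitney probability computed from
mid-ranks, identical to exhaustive pair counting with half credit for
ties (property-tested).  The gold standard is the clinical group label
when the sample carries one, else the reference full scale at the
cutoff.  Differences between dependent, overlapping correlations (two
forms against the same full scale) get Zou's (2007) 95% interval:
individual Fisher-z limits combined through the asymptotic correlation
of the two estimates; inconsistent correlation triples raise a domain
error rather than returning a complex bound.  Group descriptives use the
n−1 SD, bias-adjusted Fisher–Pearson skewness and adjusted excess
kurtosis; group comparisons use the pooled-SD d_s, Welch's t with
Satterthwaite df, and the Pearson chi-square without continuity
correction.

## Synthetic study inputs

Real Wechsler manuals' correlation and reliability tables are
proprietary, so the package generates structured stand-ins (labelled
synthetic throughout):

- `generate_battery_spec` builds `R = g g′ + s s′` (the group term only
  within an index pool) with per-subtest general loadings g and per-pool
  group increments s whose within-pool ratio to g is constant, so the
  matrix follows the exact independent-cluster higher-order model and
  the true λ_g are recoverable (the parameter-recovery test asserts
  0.05 per loading).  PSD holds by construction; reliabilities are drawn
  uniformly and floored at each subtest's communality.  The WISC-like
  presets use loading ranges ordered as in practice (verbal and
  perceptual pools most g-saturated, processing speed least), giving
  inter-subtest correlations in the 0.3–0.7 range typical of published
  batteries.
- `generate_two_group_sample` emulates the study design: 52 typical
  children drawn at the population mean, and 117 gifted children drawn
  from a mean-shifted population (shifts equal to the published gifted
  subtest means minus 10, e.g. Si +7.17, Bd +3.46) and then
  rejection-sampled on "FSIQ ≥ 125 or GAI ≥ 125".  Mean shift plus
  ascertainment is used because pure truncation of a mean-100 population
  cannot reach the published gifted subtest means.  Ages use the
  published heteroscedastic group moments (SD 12.34 vs 31.88 months) and
  sex the published proportions.  No exclusion rule is applied to the
  typical group, since none is part of the emulated design; its
  composite SD is therefore the full population 15 rather than the
  restricted SD of a convenience sample, which makes synthetic
  specificity estimates somewhat lower than an empirically restricted
  cohort would give.

What passing tests on these inputs show: that the pipeline's equating,
indices, ranking and screening behave correctly under the model's
assumptions (multivariate normality, a higher-order factor structure,
threshold ascertainment).  What they cannot show: agreement with values
that depend on the proprietary manual matrices or on the original
empirical cohort — those quantities are recomputed on the synthetic
stand-ins and reported as such.

## Numerical choices and limitations

- PSD tolerance −1e−8 on the smallest eigenvalue; an explicit
  `repair_psd` flag applies Higham-style eigenvalue clipping for
  marginally indefinite transcriptions — never silently.
- Complete-case policy: rows missing a required subtest are dropped with
  their ids logged.
- Degenerate cases (non-positive composite variance, empty C_acc
  denominator, zero-variance differences) raise or flag; NaNs are never
  silently averaged into R_c.
- ω_H values depend on the factor-model route; different software
  defaults (model, estimator, items) can move ω_H by a few hundredths on
  the same matrix, so published ω_H values are treated as regression
  fixtures, not exact targets.
- Non-goals: norm-table lookups, prorating incomplete batteries,
  copulas/non-normal marginals, confidence intervals for ω_H, ICC or
  R_c, optimal-cutoff search.
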