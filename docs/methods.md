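# Methods

## Model

All estimators share the decomposition of total cholesterol into its
lipoprotein fractions, TC = HDL-C + LDL-C + VLDL-C (all mg/dL), and
replace the unmeasured VLDL-C by TG/f:

```
LDL-C_est = (TC − HDL-C) − TG / f
```

`f` is an estimate of the TG:VLDL-C ratio. The package implements four
choices: the fixed Friedewald factor 5; an arbitrary fixed factor
(historical proposals range from 4 to 6); the McNamara step function
(4 for TG ≤ 50, 4.5 for 50 < TG ≤ 200, 5 for 200 < TG < 400); and an
adjustable factor looked up in a strata-specific median TG:VLDL-C table
indexed by TG and optionally non-HDL-C. All TG/f estimators are invalid
at TG ≥ 400 mg/dL (chylomicron interference); the ceiling is enforced in
the estimator (`OutOfValidityError`), is a property of the method rather
than the data model, and is overridable per factor table.

Table derivation inverts the same identity on a cohort with directly
measured LDL-C: per subject VLDL-C = non-HDL-C − LDL-C and the ratio
TG/VLDL-C; per stratum the cell factor is the median ratio of its
subjects. Subjects at TG ≥ 400 are excluded first; subjects whose
computed VLDL-C is ≤ 0 (measurement error makes this possible) cannot
contribute a ratio and are dropped from ratio computation only, with a
logged count — they remain valid panels elsewhere. Empty cells are stored
as NaN and refuse lookups rather than guessing.

## Binning conventions

All strata are half-open `[lo, hi)`: the band printed "50 to 99"
is `[50, 100)`, so non-integer inputs bin unambiguously, and a value
equal to an interior edge joins the upper band. The same convention
applies to the NCEP-ATP III categories (cutoff value → upper category;
70 classifies as "70 to 99"). The one deliberate exception is the
McNamara step, whose lowest band is closed above (TG ≤ 50 → factor 4) as
that method defines it. Negative estimates (possible at extreme TG with
low non-HDL-C) are returned as-is with a flag, never clipped; guideline
classification places them in "< 70". Estimates are classified unrounded;
rounding (one decimal for percentages and mg/dL, two for factors) is
applied only when formatting reports.

## Concordance accounting

Classification concordance follows the estimate-first convention: rows of
the per-category table are keyed by the **estimate's** category (its C/T
denominator is the number of subjects the estimate placed there), and a
subject is concordant when the direct measurement falls in the same
category. The direct-defined category sizes are reported alongside, which
is why a row's `n` and `T` differ. Under- and over-estimation are ordinal
comparisons of the two categories. These definitions force exact
partition identities (ΣC by category = ΣC by TG stratum = overall C;
under + over + C = T), which the tests fuzz. Rates carry Wald 95%
intervals, 100·(p ± 1.96·√(p(1−p)/T)), truncated to [0, 100], computed
from the unrounded proportion.

## Statistical tests

- **McNemar (exact)** on paired concordance indicators: with discordant
  counts (n01, n10), p = min(1, 2·P(X ≤ min(n01, n10))),
  X ~ Binomial(n01+n10, ½); symmetric, conservative, p = 1 with a warning
  when no pair is discordant. No multiplicity adjustment is applied
  across method pairs; raw p-values are reported.
- **Wilcoxon signed rank** reports SP and SN (sums of positive/negative
  ranks) so the direction of systematic over/under-estimation is
  explicit. Zero differences are dropped before midranking. For up to 25
  non-zero differences the null distribution is enumerated exactly by
  convolution over ± assignments of the (doubled, hence integer)
  midranks; above that a tie-corrected normal approximation without
  continuity correction is used. The exact path is property-tested
  against full 2ⁿ sign enumeration, the approximate path against an
  independent reference implementation.
- **Difference summaries** (estimate − direct) report median, IQR,
  5th–95th and 1st–99th percentiles using linear interpolation between
  order statistics — the dominant software convention; no rule is imposed
  by the problem itself.
- **Median CI** (per-stratum TG:VLDL-C): distribution-free
  order-statistic interval — the widest symmetric pair (x₍ₗ₎, x₍ₙ₊₁₋ₗ₎)
  with exact binomial coverage ≥ 95%. Because the coverage is discrete,
  the achieved level (e.g. 95.1% at n = 499) is reported alongside.
- **Mood's median test**: dichotomize at the pooled median (ties counted
  below), Pearson chi-square without continuity correction on the 2×k
  table; Fisher's exact test replaces it for 2×2 tables with any expected
  count under 5.
- **ANOVA + Tamhane T2** for per-stratum VLDL-C:TG means: standard F
  omnibus; all pairwise Welch t-tests with Sidak adjustment
  1 − (1 − p)^m; compact letters assigned to maximal cliques of the
  not-significantly-different graph, lettered A, B, … in descending-mean
  order so letter output mirrors the conventional table layout.
- **Variance decomposition**: OLS of computed VLDL-C on a subset of
  {TG, non-HDL-C, HDL-C, age}; per predictor the unstandardized b with
  95% CI, the zero-order correlation with VLDL-C, and the partial
  correlation computed as the correlation of residuals after regressing
  both variables on the remaining predictors; model adjusted R².
  Perfectly collinear predictor pairs are rejected by name.

## Synthetic cohorts

`generate_cohort` emulates the features the pipeline is sensitive to:

- TG lognormal (default median 106, IQR 71–157 mg/dL); an independent
  2.6% admixture with TG ≥ 400 (median 505, IQR 432–635) exercises the
  exclusion logic.
- VLDL-C:TG drawn per TG band from a Normal truncated below at 0.02
  (defaults: means 0.398/0.255/0.197/0.180/0.167, SDs
  0.178/0.091/0.055/0.048/0.041 for bands < 50 … 200–399; mean 0.15 in
  the high-TG tail). The decreasing means make the Friedewald divisor too
  small at high TG and too large at low TG, so the characteristic
  discordance pattern emerges from the ratio structure rather than being
  injected.
- VLDL-C = ratio × TG; direct LDL-C lognormal (median 111, IQR 91–133);
  HDL-C Normal(48, 10.4); TC assembled by the accounting identity, with
  optional additive assay noise (default 0).
- Sex (Bernoulli ½) and age (uniform 20–87) are uninformative
  placeholders; no pipeline stage conditions on them.

Cholesterol values are snapped to a 2⁻²⁶ mg/dL dyadic grid — far below
assay resolution — so the accounting identity and its inverse
subtractions are **exact in binary floating point**, letting tests assert
them with `==`. The truncation at 0.02 bounds TG:VLDL-C at 50, inside the
range observed in real cohorts (whose extreme ratios, up to ~286, the
generator does not reproduce; medians are insensitive to this). LDL-C and
TG are drawn independently — adequate for every property checked here,
but not a population claim.

Because the truncated Normal's median is not its mean,
`config_for_band_medians` inverts the truncated-normal median (Brent root
find) so that configured band TG:VLDL-C medians are hit exactly in
expectation. `generate_stratified_cohort` draws fixed per-band counts
(inverse-CDF within each band) for parameter-recovery experiments;
`generate_noiseless_cohort` fixes one exact ratio per band, constructing
(TG, VLDL-C) pairs whose floating-point quotient equals the requested
ratio bit-for-bit so that table derivation recovers the inputs exactly —
the oracle for the derivation machinery.

## Problem sizes and numerics

Tests and the acceptance script use a study-sized cohort of 5,642
subjects for end-to-end validation, 10,000 subjects per band for
stochastic table recovery (sampling error of a band median ≈ 0.02 ratio
units, comfortably inside the ±0.05 check), exhaustive enumeration for
the exact-test oracles (all discordant splits to n = 12; 2ⁿ sign vectors
to n = 10), and 1,000-replicate fuzzing for the partition identities.
Welch degrees of freedom use the Satterthwaite form; OLS is delegated to
a standard least-squares implementation; no iterative optimisation is
involved anywhere except the scalar Brent inversion above (tolerance
~1e-12).

## Known limitations

- The synthetic generator matches marginals and the stratum-ratio
  structure, not the joint distribution of a real population; absolute
  concordance values on synthetic cohorts are indicative, not estimates
  of any population's values.
- The adjustable-factor machinery accepts a 180-cell table as input but
  the package does not ship one; its numeric content is user-supplied.
- All quantities are mg/dL; no mmol/L conversion, no non-fasting
  adjustment, no survey weighting.
- The Wald proportion interval is used for comparability with common
  reporting practice; it is known to undercover for extreme proportions
  at small T (the truncation to [0, 100] is cosmetic, not a fix).
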