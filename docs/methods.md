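# Methods

This note documents the models, parameters, numerical conventions and design
choices behind `stroopnorm`, and what the synthetic-data tests do and do not
establish about real data.

## Normative model space and selection

For each of the twelve performance indices (T1–T4, E2–E4 and the six floored
difference indices; E1 is uniformly zero in healthy adults and is not
normed), candidate models are all OLS regressions on subsets of
{sex, age, education}. Age and education enter under one of six
transformations (identity, √, square, cube, ln, reciprocal), age optionally
under ln(100 − age); continuous covariates are centred **after**
transformation at the cohort mean of the transformed values, and sex is a
male/female contrast (female reference) centred at the male proportion.
The six-transform space has 1 + 1 + 6 + 6 + 6 + 6 + 36 + 36 = 98 models;
allowing ln(100 − age) gives 112. Enumeration order is fixed (by predictor
subset, then age transform, then education transform) and is the documented
tie-break of last resort.

BIC uses the Gaussian profile likelihood, −2 log L̂ + k ln n, with
k = slopes + intercept + residual variance. This is the convention of
mainstream statistical environments; note `statsmodels`' `bic` attribute
counts parameters differently, so the package computes its own. Selection:
candidate set = all fits within 2 BIC points of the minimum; winner = fewest
parameters, ties broken by lower BIC, then enumeration order. Bonferroni
significance flags use p·m ≤ 0.05 with m defaulting to the number of terms
in the selected model (the original family is not stated); m is
configurable.

## Corrections and norm grids

A fitted model reduces to correction terms
−Σ βⱼ (tⱼ(xⱼ) − x̄ⱼ); corrected = raw + correction. Subjects predicted
worse than the centred reference (old, low-educated for times) have the
expected deficit subtracted. Grids evaluate corrections at band midpoints —
age bands 20–24 → 22, …, 85–90 → 87.5; education 0–4 → 2, 5–8 → 6.5,
9–13 → 11, 14–19 → 16.5 — which exactly regenerates the published grid for
every internally consistent score. Display rounding is half-away-from-zero
to 2 d.p.; full precision is kept internally.

The frozen published norm set contains all twelve exact formulas,
transcribed digit-for-digit. For four scores (T4, E4, T4−T3, E4−E3) the
published formula does **not** regenerate the published grid (most starkly,
T4−T3's printed 7.15 s/year age coefficient versus the grid's ≈0.43 s/year
slope). These models are flagged `consistent=False` and the
`DemographicCorrector` defaults to grid lookup (nearest band) for them —
the table clinicians actually use — while the as-published formula remains
available under `inconsistent_mode="formula"`. The discrepancy is surfaced,
not resolved, since no intent can be inferred from the published material.
Counting note: the published methods text mentions 111 models per score,
while the published abstract and the transform combinatorics give 98 (112
with ln(100 − age)); no combinatorics tried reproduces 111, so both
supported spaces are exposed and 111 is treated as unreproducible.

## Tolerance limits and Equivalent Scores

With q = 1 − coverage (default 0.05) and B ~ Binomial(n, q), ranks are
worst-to-best:

* outer limit rank = the largest r with P(B ≥ r) ≥ confidence — the least
  conservative order statistic that still guarantees, with the stated
  confidence (default 0.95), that at most a fraction q of the population is
  worse than it. At n = 452 this is rank 15; the limit first exists at
  n = 59 (0.95⁵⁹ ≤ 0.05).
* inner limit rank = the smallest r with P(B ≤ r − 1) ≥ confidence
  (rank 31 at n = 452). The inner limit is reported but does not enter ES
  assignment.

ES = 0 beyond the OTL; ES = 4 at or better than the sample median; the
ranks strictly between the OTL rank and the median are split into three
contiguous equal-count (±1) blocks, remainders allocated toward the worse
end. Cut-offs take the sample value at the boundary rank; assignment uses
strict ">" toward the worse side and "≤" toward the better side, so tied
observations fall in the better class and collapsed (empty) classes —
present in the published cut-offs, where ES 0 and ES 1 share one value for
T1 — are skipped naturally. Both polarities run through one code path by
sign flip. Note the OTL so defined sits slightly beyond the plain 95th
percentile (at n = 10 000 its expectation for a standard normal calibration
sample is ≈1.68 rather than 1.645); that is the price of the one-sided 95%
confidence guarantee, and the test suite checks the OTL against the exact
order-statistic (beta) sampling law rather than against the naive quantile.

## ROC analyses

AUC is the rank statistic P(pos > neg) + ½P(pos = neg). Cut-point search is
exhaustive over midpoints of adjacent distinct pooled values plus ±∞, with
"strictly above the cut-point indicates pathology". Youden ties are broken
toward higher specificity (a normative context favours specificity), then
the lower cut-point; with that convention a contrast where no cut-point
beats chance resolves to the all-negative classifier (sensitivity 0,
specificity 1) without error, and ratios with empty denominators (e.g. PPV
with no positive calls) are reported as missing, never as 0.

## Power analysis

`required_n_f2` solves the denominator df v of the F-test of u regressors
with noncentrality λ = f2·(u + v + 1) for the requested power, by bracketed
root-finding on the (monotone) noncentral-F power function. Reporting
conventions differ: R's `pwr.f2.test` quotes v itself (363.35 → 363 at
u = 3, f2 = 0.03, α = 0.05, power = 0.80), while the total regression
sample size is u + v + 1 (367.35 → 367). `PowerResult` returns both
(`n_suggested`, `n_total`), and the acceptance script reports the
`pwr`-convention value.

## Synthetic cohorts: what they emulate

Demographics reproduce the published stratum table exactly (452
participants, 200 male / 252 female, 14 age bands × 4 education bands);
ages and education are integer-uniform within bands, education floored at 1
year so logarithmic/reciprocal terms stay defined (the 0–4-years stratum is
included by default and can be excluded). `scaled_stratum_counts` rescales
the mixture to other sample sizes.

Completion times follow the selected normative forms
(ln-education + cubic-age) with Gaussian noise truncated at a 1 s floor.
Slopes are the published coefficients; for T4 and E4, whose published
formulas are the inconsistent ones, slopes were derived from the published
grid geometry (T4: −11.388 per ln-year, 7.581·10⁻⁵ per year³; E4: −1.0094,
5.506·10⁻⁶), which reproduces the printed grid corners to ~0.01. Residual
SDs are the printed marginal SDs × √(1 − R²) of the selected models (e.g.
T4: 20.781·√0.43 ≈ 13.63 s). Intercepts are calibrated constants such that
the default stratum mixture reproduces the printed means (Task 1 24.701 s …
Task 4 61.252 s). Error counts are beta-binomial over the 50 items (the
printed SDs are overdispersed relative to a binomial; ρ per task from the
printed mean/SD), with mild demographic effects on the mean count for
E2–E4; the published E2 age coefficient is larger than the E2 mean count
itself and would be unusable as a count-mean effect, so E2 uses the
E3-scale effect instead. Task 1 errors are identically zero.

AD and MCI cohorts are additive deficits on tasks 3 and 4 only (the
clinical data are retrospective and carry only those tasks): defaults
AD +45 s/+8 errors on T4, +15 s/+2 on T3; MCI +18/+3 and +5/+0.7 —
magnitudes chosen to produce the qualitative ordering healthy < MCI < AD
with strong T4 discrimination, and configurable. Patient demographics are
drawn from normal distributions around the published clinical means.

What passing tests show: the pipeline's operations are correct against
independent oracles, the selection machinery recovers a known truth at
n ≈ 2000 in ≥80% of replicates, and the tolerance machinery meets its
coverage guarantee. What they do not show: that real Stroop data follow
these generating forms, that real residuals are Gaussian, or that the
published Table values for cut-offs and ROC metrics are themselves
reproducible — those depend on the original raw cohort, which is not
deposited.

## Numerical conventions and degenerate inputs

Difference indices are floored at zero before model fitting (the recode is
applied at the dependent-variable stage); missing raw scores propagate as
missing indices and are never imputed. Rank-deficient designs and transform
domain violations are rejected with named diagnostics, not silently
dropped. A noise-free fit has BIC −∞ (it wins any comparison). All-equal
calibration samples yield degenerate, flagged tolerance bands. Cohort
generation and every CLI artifact are pure functions of (configuration,
seed); CSV round-trips use round-trip float parsing.

## Problem sizes used by the test suite

Calibration checks use 1000 simulated samples of n = 452 for the coverage
guarantee, 50 replicates of n ≈ 2000 cohorts for transform recovery, 40
replicates of n = 10 000 for the OTL sampling-law check, and exhaustive
rank scans for n = 59…500 — sizes at which the Monte-Carlo error of each
assertion is small relative to its tolerance.
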