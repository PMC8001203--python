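# Methods

This note records the statistical model behind each stage, the defaults and
why they hold, the numerical choices, and what the synthetic-data tests do
and do not establish about real cohorts.

## Data model

Genotypes are unphased diploid allele counts per variant: 0 (common
homozygote), 1 (heterozygote), 2 (rare homozygote), −1 missing.  File
readers keep the standard ALT-count convention; `GenotypeMatrix.orient_minor`
flips a column exactly once, on the full cohort, so that downstream code
counts the minor allele.  Fixing orientation on the full cohort (not per
subgroup) prevents an allele-frequency excursion past 0.5 inside a small
stratum from silently swapping the reference genotype group between
analyses.  Multi-allelic sites are rejected at read time and must be split
upstream; phased separators are accepted and ignored.

The clinical record carries: binary therapy response (good = complete or
partial remission, poor = stable/progressive disease), defined only for
neoadjuvant-chemotherapy (NACT) patients; disease-free survival in months
with an event flag; therapy group (NACT, adjuvant cytotoxic, hormonal-only,
none); intrinsic subtype (Luminal A/B, HER2-enriched, TNBC); and four
covariates (tumor size, grade, nodal status, ER status).

## Per-variant statistics

**MAF** = (n_het + 2 n_rare-hom) / (2 n_called), folded to ≤ 0.5.

**Hardy–Weinberg.**  Default is the 1-df Pearson chi-square against the
p², 2pq, q² expectation — the test most common in candidate-gene panels of
this size; a conditional-on-allele-counts exact test (probabilities from
the stable ratio recurrence, summing configurations no more probable than
the observed) is selectable via `hwe_method="exact"`.  On
equilibrium-consistent simulations at n = 500 the two agree in ≥ 95% of
accept/reject decisions at α = 0.01.  Monomorphic variants return p = 1 by
convention: no departure is testable.

**Genetic models.**  The codominant model keeps the three genotype groups;
the carrier model pools heterozygotes with rare homozygotes.  The selection
rule is frequency-driven: when rare homozygotes in the *analysis subset*
number fewer than `min_homozygotes` (default 5), the carrier collapse is
used to preserve power.  The count is taken from the subset actually tested
(e.g. the NACT subgroup), not the full cohort, because that is where the
expected-cell-count problem arises.  The literature labels this collapse
inconsistently ("dominant" or "recessive" depending on which allele is
taken as reference); the package uses the neutral term *carrier*.

## Response association

Genotype group × good/poor contingency tables are tested by the Pearson
chi-square without continuity correction (df = (rows−1)(cols−1)); the
uncorrected statistic is the standard choice at these sample sizes and is
what the reference confirmation-set tables reproduce exactly.  Odds ratios
are the 2×2 cross-product — poor-response odds in the rare/carrier group
over the common-homozygote group — with Woolf (log-OR ± 1.96·SE)
confidence intervals.  When the tested table has three rows the odds ratio
is reported on the carrier collapse, as a single summary per variant.  A
zero cell triggers the Haldane–Anscombe +0.5 correction on all four cells
with an explicit flag; a zero row or column margin makes the OR undefined
and is flagged rather than corrected.

## Survival analysis

Follow-up is administratively capped at 120 months: later times become
censored observations at the cap (idempotent; a time exactly at the cap
keeps its event flag).

The k-group log-rank statistic is computed from the pooled risk sets with
hypergeometric variance and simultaneous tie handling, as a quadratic form
over the first k−1 groups.  It is implemented directly in numpy because the
permutation null re-evaluates it B times per variant; the implementation is
tested to 1e−10 agreement against an independent library implementation,
including heavily tied (month-resolution) times.

The permutation-adjusted p-value permutes group labels against the fixed
(time, event) pairs — equivalent under exchangeability to permuting the
outcome pairs — and uses the add-one estimator (1 + #{T\* ≥ T})/(B + 1), so
the smallest attainable value is 1/(B+1) and p = 0 is impossible.  B
defaults to 100; tests that need a stable null distribution use larger B.

**Gene dosage.**  The plausibility filter asks whether survival is ordered
with 0/1/2 copies of the minor allele.  "Ordered" is operationalized as
monotonicity (ties allowed, either direction) of the restricted mean
survival time to the 120-month horizon: RMST is well-defined under heavy
administrative censoring, unlike medians, and summarizes each Kaplan–Meier
curve in one number.  If any genotype group has fewer than `min_group` (5)
subjects, a three-group ordering is not assessable: the check collapses to
carrier status and passes with the direction marked "collapsed".

**Cox proportional hazards.**  Multivariate fits use the partial likelihood
with Efron tie handling (appropriate for month-resolution ties).  Listwise
deletion is applied first and the retained sample and event counts are
reported; constant covariates are dropped with a warning; non-convergence
(including separation) is flagged on the result, never silent.  The
genotype enters as an allele count under the codominant/additive model or
as a carrier indicator after collapse.

**ANOVA.**  Genotype–transcript-level associations use the classical
one-way F test.

## Multiple testing

Benjamini–Hochberg step-up adjusted p-values, capped at 1, original order
preserved.  The test family in the confirmation phase is the variant panel
within one endpoint × one stratum; the family choice is configurable
because published analyses of this design rarely state theirs, and family
size materially changes adjusted values.

## The two-phase pipeline

Evaluation phase order: HWE → MAF → missingness → association screens
(union of response and DFS hits, both permutation-adjusted) → LD tag
pruning → dosage filter (DFS hits only).  The three QC filters are pure
per-variant predicates, so the surviving set is invariant to their order
(asserted in tests); the recorded *fate* uses the cascade order above.
Every input variant receives exactly one fate and the stage counts sum to
the input count — the audit-trail conservation property.

Tag pruning is greedy: hits are visited by ascending adjusted p (ties by
variant id); each selected representative absorbs all unassigned variants
with r² above the threshold.  Best-p-first matches the design's intent of
keeping the most associated member of each LD clump and makes the result
deterministic.  Assay-replacement (`replace_failed_assays`) is an explicit
step taking the list of failed variant ids and searching all cohort
variants for the best proxy with r² ≥ 1 by default.

The dosage filter applies only to DFS-associated representatives: a
response-associated variant needs no survival-dosage plausibility.

## Linkage disequilibrium

r² and D′ are defined on maximum-likelihood two-locus haplotype
frequencies estimated by EM over the double-heterozygote phase ambiguity
(the convention of haplotype-tagging software), not on genotype
correlation; a composite genotype-correlation r² is available separately
as `genotype_r2`.  The EM E-step splits the ambiguous chromosomes between
cis and trans phase in proportion to the current product frequencies;
initialization is the linkage-equilibrium product, convergence is declared
at 1e−8 in frequencies and log-likelihood.  Properties verified by tests:
the log-likelihood never decreases; fitted marginals equal observed allele
frequencies; with no double heterozygote the solution equals the
phase-known haplotype counts exactly; with ambiguity the r² matches a
one-parameter likelihood-grid oracle within 1e−4.  Monomorphic members
return r² = 0 with a warning.

## Synthetic cohorts

The generator draws, per haplotype block, two haplotypes per sample from
the block's haplotype frequencies — so Hardy–Weinberg holds at every
variant by construction and within-block LD is exactly the
haplotype-frequency-implied value in expectation.  Response is Bernoulli
through a logistic link (baseline log-odds of poor response plus per-copy
effects), drawn only for NACT-assigned samples.  Survival is exponential
proportional hazards (constant baseline hazard; a Weibull shape parameter
is exposed for non-constant hazards), with independent exponential
censoring and the 120-month administrative cap.  Per-genotype (3-tuple)
survival effects allow deliberately non-additive truths such as the
dosage-violating fixture.  Genotype missingness is MCAR only.  Covariates
are independent of genotype by default (no confounding).

Defaults describe a realistic breast-cancer cohort: ~21% NACT / 46%
adjuvant cytotoxic / 23% hormonal-only / 10% no further therapy; a
luminal-dominated subtype mix; baseline hazard 0.005 relapses/month
(median DFS well beyond the cap for most patients) and censoring rate
0.008/month.  Fixture effect sizes (e.g. per-copy OR 4 in
`strong_response_effect`) are chosen for test power, not to mimic any
particular study's estimates, which are mostly unpublished on the OR/HR
scale.

One integer seed determines a cohort; each stage (haplotypes, missingness,
therapy, response, survival, subtype, covariates) draws from its own
deterministically derived sub-stream, so adding a variant to the
configuration never perturbs the clinical draws, and identical seeds give
byte-identical cohorts.

**What passing synthetic tests does not show.**  The generator has no
population stratification or relatedness, no genotype–covariate
confounding by default, MCAR (not informative) missingness, no
measurement/batch effects, and exponential event times.  Calibration and
power measured here therefore speak to the correctness of the statistics,
not to their robustness against those real-data features.

## Numerical choices and degenerate inputs

- Permutation p-values use the add-one estimator; comparisons use a 1e−12
  slack so a permuted statistic numerically equal to the observed one
  counts as exceeding.
- Chi-square tables with a zero row/column margin raise an error naming
  the margin; per-variant scans convert such errors into skip records with
  a reason instead of aborting.
- RMST monotonicity allows ties at 1e−9.
- The log-rank quadratic form falls back to a pseudo-inverse if the
  covariance block is singular; the statistic is floored at 0.
- Cox confidence bounds may overflow to infinity under near-separation;
  this is reported as-is together with the convergence flag.
- Report writers are deterministic: fixed column order, floats at 6
  significant digits, no timestamps.

## Problem sizes in tests

The statistical acceptance checks use: 1000 null variants at n = 300 for
type-I error of the response test; 1000 (500 in the acceptance script)
two-group null datasets of n = 40 with B = 100 for permutation validity;
n = 5000 for Cox recovery of log HR = ln 2 (tolerance 0.1); 10⁴ random
vectors for the FDR step-up identity at 1e−12; a 240-sample, 8-variant
known-fates cohort for the audit trail.  These sizes give binomial/Monte
Carlo noise comfortably inside the asserted tolerances while keeping the
default test run fast.

## Known limitations

- Two-locus haplotype estimation only; no multi-locus blocks or phased
  input.
- No logistic regression with covariates for the response endpoint (the
  design adjusts only survival analyses).
- Cox fits support Efron tie handling only.
- No proportional-hazards diagnostics, time-varying covariates, competing
  risks, or overall-survival endpoint.
- The evaluation-phase variant counts of any particular published study
  are not reproducible without its raw sequencing data; the pipeline
  reproduces the *procedure*, with synthetic ground truth standing in for
  the cohort.
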