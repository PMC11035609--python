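# Methods

This note documents the models behind `wbcpgs`, the conventions fixed
where several were defensible, and the limits of what the synthetic
experiments demonstrate.

## Score construction

The score is the standard weighted allele-dosage sum.  Conventions:

* **QC filter.** Retained iff `p < p_max`, `min(eaf, 1−eaf) > maf_min`
  (strict), `info ≥ info_min`, and the allele pair is not A/T or C/G.
  Palindromic pairs are removed because their strand is ambiguous when
  transferring weights between datasets.
* **Clumping.** Greedy by ascending association p with a deterministic
  tie-break (smaller p, then lexicographic variant id): the best
  remaining variant is retained and all remaining variants with squared
  dosage correlation ≥ `r2_max` (default 0.01) against it are dropped.
  LD r² is the squared Pearson correlation of dosage columns in the
  supplied reference panel.
* **Region exclusion.** The MHC interval 6:25,500,000–33,500,000 is
  treated as 1-based inclusive at both ends.
* **Catalog-LD exclusion** runs after clumping (it purges the
  already-built score) and drops a variant iff some catalog entry with
  `p < 5×10⁻⁷` has r² strictly greater than 0.5 with it.  Catalog
  variants absent from the panel are skipped with a warning, not an
  error.
* **Scoring.** A model variant whose effect allele matches the panel's
  other allele has dosage flipped to `2−d` (logged); matching neither
  allele is an error.  Missing dosages are mean-imputed per variant.
  Standardization uses the reference cohort's mean and sample s.d.
  (ddof = 1), stored on the model; each analysis cohort is standardized
  separately.
* **Threshold selection** rebuilds the full chain per candidate
  threshold and picks the highest partial correlation (correlation of
  least-squares residuals after adjusting both variables on the
  covariates) between the standardized score and median WBC; ties break
  toward the most stringent threshold.  The covariate list is
  configurable (defaults to age and sex; the reporting stages use age,
  sex and 5 principal components).

## Quintile diagnostics

Variants are ranked by effect-size magnitude |w| with ties broken by
variant id and assigned to quintiles by rank cuts at the
20/40/60/80th percentiles, so sizes differ by at most one and quintile
sub-scores sum exactly to the full score.

**Permutation test.**  What a "permutation of a quintile score" should
permute is genuinely open; the default here resamples same-size variant
subsets from the full model (preserving the score-construction
structure, including LD among sampled variants), with a person-label
permutation mode behind a flag.  The empiric p uses the add-one rule
`(k+1)/(B+1)`, which can never return 0 and prints 0.001 when nothing
among 1000 permutations reaches the observed count.  The observed
statistic counts phenotypes with a nominal (p < 0.05) association in
the positive direction by default; any-direction counting is a switch.

**Engine.**  Inside the permutation and per-SNP machinery, associations
are assessed with the Rao score test from a covariate-only logistic
null fit: the null model is fitted once per phenotype and the efficient
score statistic is then closed-form for every candidate score column,
making hundreds of permutations × hundreds of phenotypes feasible on
one CPU.  The score test is asymptotically equivalent to the Wald test
used by the reporting scan (`clinassoc.logistic_fit`, full ML via
statsmodels); the two engines are cross-checked in the tests.  Using
one engine for observed and permuted columns alike keeps them exactly
exchangeable.

**Calibration and discreteness.**  The count-of-nominal-associations
statistic is integer-valued, so the permutation p is conservative: its
sub-α mass is strictly below α and approaches the continuous-case limit
(9/200 = 0.045 for p < 0.05 at B = 199) only as the phenotype panel
grows.  The calibration study therefore uses 500 independent null
phenotypes (400 people, prevalence 0.3, any-direction counting), chosen
analytically before any simulation was run: the expected fraction of
replicates with p < 0.05 is 0.0271 at 15 phenotypes, 0.0354 at 300, and
0.0371 at 500 (exact binomial mixture computation).  At a realistic
15-phenotype panel the empiric p is markedly conservative — a property
of the method, worth knowing before interpreting borderline empiric
probabilities near 0.05.

**Binomial enrichment.**  Per phenotype, the number k of a quintile's
SNPs individually associated at p < 0.05 is compared with the exact
tail `P(X ≥ k)`, `X ~ Binomial(n_q, 0.05)` (scipy's regularized
incomplete beta; agrees with rational-arithmetic summation to 1e-12).

## Reference ranges

Per-person summaries use the median (and separately the lowest)
surviving count after excluding counts above 35,000 cells/µL; the
assay-outlier flag is any surviving count *strictly below* its assay's
lower bound.  Percentile curves report the 5th/50th/95th percentiles of
the summary value within ±0.2 s.d. score windows.  The
genotype-informed threshold for a biopsied person is the 2.5th
percentile of the *lowest-observed* WBC among reference-cohort members
within ±0.2 s.d. of their score, and "within range" means count **at or
above** the threshold; the strictly-above variant is a flag, since the
sources for this rule disagree between "above" and "at or above", and
the at-or-above reading is implemented as the default.  Quantiles use
linear interpolation between order statistics (numpy's default) —
no convention was stated, so one is fixed and the test oracles use the
same one.  Windows need at least `min_n = 20` members (a 2.5th
percentile needs tail support); thinner windows are surfaced as
unclassifiable rather than silently out-of-range.  Strata are half-open
`(lo, hi]`, percentages print to one decimal.

## Clinical association stages

* Logistic and linear stages are full-ML statsmodels fits; estimates
  are OR per s.d. (or slope per s.d. on the log scale) with Wald 95%
  intervals.  Age-squared enters only the assay-outlier / diagnosis-code
  logistic stages; other stages use age linearly.  Perfect separation
  and non-convergence raise, with diagnostics attached.
* Hosmer–Lemeshow uses 8 equal-count deciles-of-risk bins (ties kept
  together; degrees of freedom = bins − 2, recomputed if ties collapse
  bins).  No installed package provides this test, so it is implemented
  here and its null uniformity is simulation-tested.
* Exposure cohorts: the event is the first post-baseline day with a
  count below the outcome threshold (default 3000 cells/µL; 3500/4000
  and ANC 1500 supported); censoring at the earliest of second
  treatment cycle, the horizon, or last encounter.  "1 month" is fixed
  at 30 days and "24 months" at 730 days.  Persons with baseline count
  ≤ 1000 cells/µL are excluded and logged.
* Cox fits use lifelines with Efron handling of ties (its default);
  diagnostics summarize Schoenfeld (proportionality p), martingale
  (correlation with the score, non-linearity) and deviance (outlier
  fraction) residuals.  Dose and duration enter the taxane model as
  baseline covariates, not time-varying ones.
* Kaplan–Meier strata: Low (score < −1), Middle (−1 ≤ score ≤ 1,
  boundaries inclusive), High (score > 1).

## Synthetic-data generator

The studies this pipeline serves use access-restricted biobank data, so
every generative choice below is a stand-in with the statistical
structure the analysis assumes, not a model of any real cohort.

* **LD.**  Blocks of variants share an allele frequency drawn from
  `maf_range`; each haplotype copy equals a block-level lead allele
  with probability √`block_ld`, else an independent draw.  Pairwise
  dosage correlation within a block is then exactly `block_ld`
  (r² = `block_ld`²); blocks are independent.  Frequencies are
  therefore drawn at block granularity — the price of an exact,
  testable correlation target.  Real human LD (decaying with distance,
  frequency-heterogeneous) is deliberately out of scope.
* **GWAS.**  `n_causal` variants get effects ~ N(0, `effect_sd`²) on
  log-WBC; a fresh discovery cohort of `gwas_n` people yields
  single-variant least-squares β, SE and p.  The default `gwas_n` is
  20,000 — scaled down from the ~750,000-participant source GWAS the
  real score is built from, so the default score retains tens of
  variants rather than 1739.  `effect_sd` = 0.06 makes the simulated
  heritable fraction of log-WBC ≈ 0.15.
* **WBC phenotype.**  Log-normal with mean 8200 and s.d. 3900 cells/µL
  (σ²_log = 0.204 split into between-person 0.392², within-person
  0.18², and score 0.133²); counts round to multiples of 100 as assays
  report, the assay lower bound defaults to 3900 cells/µL, and each
  person has 1 + Poisson(2) measures.  The score effect γ = 0.133 was
  derived once, analytically, so the partial correlation between score
  and median WBC is ≈ 0.29 at the 11,694-person cohort scale (allowing
  for the median over repeated measures and the log-normal attenuation).
* **Cohorts.**  Age ~ N(57, 17²) truncated to [18, 90], 55% female,
  PCs standard normal.  Biopsy cohort: pathology ~ Bernoulli(0.30)
  *independent of the score*; normal-outcome biopsy counts track the
  person's genetic expectation, abnormal-outcome counts are
  disease-driven and lower; comorbidity rates 83% vs 45%.  Exposure
  cohorts: event day exponential with rate `hazard_baseline`/30 ·
  exp(θ·score) per day; taxane defaults θ = ln 0.78 with baseline 0.25
  events/person-month (≈16% events inside the ~21-day first cycle);
  azathioprine discontinuation θ = ln 0.62 with baseline 0.0025 (≈3%
  events within 24 months).
* **Worked-example fixture.**  `worked_example_fixture` is a deterministic
  biopsy cohort in which every biopsied person has an isolated
  40-member reference window whose lowest-count distribution pins the
  2.5th-percentile threshold exactly at (within-range) or just above
  (out-of-range) their biopsy count, reproducing the reference
  stratified table cell-for-cell and exercising the at-or-above
  boundary.

**What passing tests show — and don't.**  Parameter recovery, oracle
equivalence and calibration on these generators establish that the
*implementation* is correct under the stated models.  They do not
establish robustness to real-data features the generators omit:
distance-decaying LD, ancestry structure beyond noise PCs, informative
censoring, assay drift over time, or correlated phenotypes in the
phenome scan.

## Problem sizes

Default test and acceptance runs use the cohort sizes above
(11,694 / 1724 / 1180 / 117) with a 1200-variant, 300-block panel and a
20,000-person discovery GWAS; recovery studies use 200 replicates and
the permutation calibration 200 replicates × 199 permutations.  The
numbered analysis scripts use a further-reduced 600-variant /
3000-person configuration so the whole chain replays in seconds.
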