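# Methods

`chipscan` implements a genetics-first screen for inflammatory genes that
modify the cardiovascular risk carried by clonal hematopoiesis of
indeterminate potential (CHIP).  The procedure has four stages — predicted
expression score construction, score tuning, CHIP annotation, and a
stratified survival interaction scan — plus a synthetic cohort generator
that stands in for the restricted biobank data the design targets.

## Predicted expression scores (pruning + thresholding)

For each gene the score of individual *i* is

    PES_i = Σ_j  β̂_j · G_ij ,    j ∈ S_clump(r_c², w_c),  p_j < p_r

where β̂_j and p_j come from external cis-eQTL summary statistics (cis =
±500 kb around the TSS), G_ij is the allele dosage aligned to the effect
allele, and S_clump is the set of index variants surviving greedy LD
clumping against a reference panel: variants are promoted in ascending
P-value order and absorb every remaining variant within w_c bp (inclusive,
both sides) whose reference r² with the index is ≥ r_c².  The candidate
grid crosses r_c² ∈ {0.1, 0.01, 0.001}, p_r ∈ {5×10⁻⁸, 1×10⁻⁵, 10⁻³,
10⁻², 0.1} and w_c ∈ {250 kb, 5 Mb} — 30 configurations per gene.

Conventions that matter and are fixed here:

- **Clumping precedes thresholding.** The indicator is applied inside the
  clumped set; reversing the order changes which proxies absorb which hits.
- **Strict inequalities** for the P threshold (`p_j < p_r`), mirroring the
  indicator's definition.
- **Tie-break**: equal P values order by ascending (chrom, pos), so results
  are invariant to input record order.  Summary statistics additionally
  carry `log10_pvalue`; clumping orders on it when present because
  biobank-scale marginal statistics underflow double-precision P values,
  which would otherwise collapse the ordering into a position tie.
- **Allele harmonization**: records are matched to genotypes on chrom:pos;
  swapped alleles flip the sign of β̂ (and the EAF); strand-ambiguous
  (A/T, C/G) variants are dropped by default; mismatches are dropped and
  counted.
- **Missing dosages** are mean-imputed per variant from the cohort.
- **Standardization** uses the population SD convention (denominator n) and
  may be computed on a stated sub-population (e.g. one ancestry stratum);
  constant scores are flagged degenerate and zeroed.
- **Shrinkage-weight plug-in**: externally computed per-variant posterior
  weights (e.g. from a continuous-shrinkage method over its global grid
  10⁻⁶, 10⁻⁴, 10⁻², 1) can be scored through `build_weighted_score`; the
  shrinkage machinery itself is out of scope.

## Score tuning

Every candidate is evaluated in one or more validation cohorts with
measured expression.  Expression is first residualized on covariates (a
linear fit; the default adjustment set is age, sex and PCs when supplied —
the exact published adjustment is not recoverable, so it is configurable)
and re-standardized; r² is the squared Pearson correlation between the
candidate score and adjusted expression over ≥ 30 overlapping samples.  The
selected score is the argmax over configurations × cohorts (ties break
toward grid order), and a gene is retained for the scan only when its best
r² strictly exceeds 1%.

## CHIP annotation

A sample carries CHIP when it holds ≥ 1 somatic variant in a whitelisted
driver gene at VAF **strictly** greater than 2%; a clone is *large* at VAF
strictly greater than 10%.  The whitelist ships as a versioned YAML
(common myeloid drivers by default: DNMT3A, TET2, ASXL1, JAK2, SRSF2,
SF3B1, TP53, PPM1D, plus an OTHER bucket); a fuller curated panel drops in
with the same schema, including per-gene variant-class restrictions.
Derived per-sample variables: the composite indicator, per-gene
indicators, the large-clone indicator, and the driver count.  Annotation is
idempotent and every exclusion is counted by reason.

## Stratified scan, carry-forward, interaction, FDR

All survival models are Cox proportional-hazards fits adjusted for age,
sex, ancestry, BMI, type-2 diabetes, ever-smoking and 10 genetic PCs, with
complete-case filtering (the removed fraction is reported), Efron tie
handling, and two-tailed Wald tests.

1. For each (CHIP variable, gene) pair the per-SD score association is fit
   separately among carriers and non-carriers.
2. A pair is **carried forward** when the score associates with the outcome
   at P < 0.05 among carriers *and not* among non-carriers (two-clause
   reading; the one-clause variant — carrier significance only — is
   selectable because the published wording is ambiguous).
3. Carried-forward pairs get one hierarchical interaction model
   (covariates + score + CHIP + product); the product term's Wald z/P are
   the interaction statistics, with Benjamini–Hochberg FDR across the
   carried-forward family (the family choice is configurable).
4. The exploratory trait scan associates each flagged pair's score with 31
   hematologic and 5 cardiometabolic quantitative traits among carriers,
   using linear models on log₂-transformed, zero-mean/unit-variance traits
   (CRP gets +1 before the log to absorb zero measurements; non-positive
   values after offset are dropped and counted; a constant transformed
   trait is degenerate and skipped).  FDR is controlled separately within
   the two families, so k flagged pairs give k×31 and k×5 tests.  Linear
   models are used deliberately: the survival-model wording in the source
   description is not meaningful for quantitative outcomes.

### Cox solver

`fit_cox` wraps an own vectorized Newton–Raphson maximizer of the Efron
partial likelihood (`chipscan.cox`).  Risk sets are nested prefixes of the
descending-time order, so the gradient and observed information reduce to
cumulative sums and two weighted Gram matrices per iteration; a fit at
n = 20,000 with 16 covariates takes ~0.1 s and small models take ~10 ms,
which is what makes the 1000-replicate calibration experiments practical.
Step-halving guards the ascent; standard errors come from the inverse
observed information; non-convergence and separation are flagged, and
flagged fits are excluded downstream with a reason.  The test suite
cross-checks coefficients, standard errors and log-likelihood against
`lifelines.CoxPHFitter` to ~1e-6.

## Synthetic cohort generator

The generator emulates the *structure* of the target data, not its content:

- **Genotypes**: Gaussian-copula haplotype blocks.  Within a block, latent
  normals are equicorrelated at the value obtained by tetrachoric inversion
  of the target allele correlation (one MAF per block, drawn from the
  configured range, shared by all panels generated under the same seed so
  reference, cohort, validation and external panels sample one population);
  blocks are independent.  Haplotypes are thresholded to alleles and paired
  into diploid dosages.
- **Expression**: standardized genetic value × √h² + noise × √(1−h²), so
  the cis-heritability is exact by construction.  The default gene set
  plants h² = 0.35 for the best gene, mirroring the top observed variance
  explained (~35%) in the family of scores the pipeline emulates.
- **Summary statistics**: marginal per-variant OLS in an independently
  simulated external panel (default n = 30,000), with exact t-based P
  values, log-scale P values, and explicit effect alleles; monomorphic
  variants are emitted with missing effect fields.
- **CHIP**: composite carrier status Bernoulli(6.2%); carriers draw one
  driver (two with probability 7.4%) from gene weights fixed-point-adjusted
  so realized per-gene marginals match the stated prevalences (55.4% of
  carriers DNMT3A, 19.9% TET2, 9.1% ASXL1, 1.0% JAK2, remainder spread
  over SRSF2/SF3B1/TP53/PPM1D/other).  Clone sizes are Beta-distributed,
  truncated to [0.02, 1]; JAK2 uses Beta(4, 9) so ~97% of JAK2 carriers
  are large clones, other genes Beta(1, 14) (~30% large).  An optional
  age-logit tilt on carrier probability is off by default.
- **Covariates**: age N(56.3, 8.1); sex Bernoulli(0.444 male); ancestry
  Bernoulli(0.90); BMI N(27.4, 4.8); ever-smoker Bernoulli(0.45); type-2
  diabetes Bernoulli(0.05); 10 standard-normal PCs.
- **Survival**: exponential event times with rate
  `baseline_hazard × exp(lp)`, where lp sums covariate, CHIP, score and
  CHIP×score product log-hazards; censoring at the earlier of a 12-year
  administrative horizon and exponential dropout (~5% loss).  The baseline
  rate is calibrated by root-finding so the marginal event fraction hits
  its target (default 10.6%).  Planted defaults: composite-CHIP log(1.18),
  non-carrier score log(0.99), carrier-only interaction log(1.85) on the
  AIM2-like gene.
- **Traits**: independent log-normal noise (no planted associations); CRP
  has a ~5% point mass at zero to exercise the +1 offset.
- **Seeding**: one master seed fans out to named counter-based streams, so
  every artifact is byte-reproducible and streams are independent.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: realistic recombination and fine-scale LD,
population admixture and ancestry-specific LD references, clonal dynamics
over time, genotyping/imputation error, correlated trait panels, and
age-dependent confounding beyond the optional logit tilt.

## Validation experiments and problem sizes

`chipscan.experiments` drives the Monte-Carlo checks used by both the test
suite and `scripts/acceptance.py` (same code path):

- **Type-I error** of the interaction Wald test: 1000 null replicates at
  n = 20,000, 5% carriers, ~10% events; the rejection rate at α = 0.05 is
  expected in [0.035, 0.065].  Calibration fits adjust for age and sex —
  the planted covariate effects — since the test's level does not depend
  on the full covariate battery.
- **CI coverage**: 200 replicates with planted carrier-stratum HR 1.85;
  95% CIs for the carrier-stratum effect and the interaction log-HR should
  cover ≥ 90% of the time.
- **Tuning recovery**: a single-causal-variant gene with h² = 0.35,
  external n = 30,000, validation n = 5,000; the tuned best r² lands
  within ±0.07 of 0.35.
- **End-to-end smoke**: 50 seeded 10,000-sample pipeline runs; the planted
  carrier-only pair should be carried forward and FDR-significant in
  ≥ 80% of runs.

These sizes keep the full suite within a few minutes on one CPU while
leaving the Monte-Carlo error well inside each criterion's tolerance.

## Known limitations

- One LD reference per run; ancestry-stratified scoring is supported via
  sub-population standardization but multi-reference workflows are not.
- The greedy clumping is O(m²) in the worst case per window; fine for the
  cis-window problem sizes it targets (tens to hundreds of variants).
- No proportional-hazards diagnostics beyond convergence flags; competing
  risks are out of scope (an alternative endpoint column is accepted).
- Cohort size is a free parameter; the generator does not take a stance on
  the published enrollment-versus-analysis count discrepancy.
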