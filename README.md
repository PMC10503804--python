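# chipscan

Clonal hematopoiesis of indeterminate potential (CHIP) — age-related clonal
expansion of blood cells carrying somatic driver mutations (DNMT3A, TET2,
ASXL1, JAK2, …) — raises cardiovascular disease (CVD) risk, plausibly
through inflammasome signalling.  `chipscan` implements a genetics-first
screen for inflammatory genes that *modify* that risk: instead of
correlating measured biomarkers with outcomes, it builds genotype-based
predicted expression scores for candidate genes and asks whether a 1-SD
increase in predicted expression changes CVD hazard specifically among CHIP
carriers.

It is written for statistical geneticists and cardiovascular
epidemiologists who want the full procedure — score construction, tuning,
CHIP annotation, and the stratified interaction scan — as a tested,
reusable pipeline, exercised end to end on a synthetic biobank cohort
generator (the real data the design targets are access-restricted).

## The method

**Scores.** For each gene, a pruning + thresholding (P+T) score

> PES_i = Σ_j β̂_j · G_ij over j ∈ S_clump(r_c², w_c) with p_j < p_r

is built from external cis-eQTL summary statistics (cis = ±500 kb of the
TSS): greedy LD clumping against a reference panel keeps index variants,
a strict P-value indicator selects among them, and the weighted
allele-dosage sum is standardized to zero mean, unit variance.  A grid of
3 r² levels × 5 P thresholds × 2 windows gives 30 candidates per gene; the
candidate explaining the most measured-expression variance (r²) in a
validation cohort wins, and genes with best r² > 1% are retained.

**CHIP.** Samples carrying a whitelisted driver mutation at variant allele
fraction (VAF) > 2% are CHIP carriers; clones with VAF > 10% are "large".
Derived variables: composite CHIP, per-gene indicators, large-clone flag.

**Scan.** Per (CHIP variable, gene score) pair, covariate-adjusted Cox
models (age, sex, ancestry, BMI, type-2 diabetes, smoking, 10 PCs) are fit
separately among carriers and non-carriers.  Pairs significant among
carriers (P < 0.05) and not among non-carriers are carried forward to a
hierarchical interaction model (score + CHIP + product); Benjamini–Hochberg
FDR is applied across the carried-forward family, and flagged pairs get an
exploratory scan over 31 hematologic + 5 cardiometabolic traits
(log₂-transformed, standardized; FDR within each family).

See `docs/methods.md` for conventions, the synthetic-data model, and the
validation experiments.

## Worked example

```python
import chipscan

result = chipscan.run_pipeline(seed=1)

row = result.stratified.query("chip_variable == 'has_chip' and gene == 'AIM2'").iloc[0]
print(f"carriers:     HR {row.hr_present:.2f} "
      f"({row.ci_low_present:.2f}-{row.ci_high_present:.2f}), P = {row.p_present:.1e}")
print(f"non-carriers: HR {row.hr_absent:.3f}, P = {row.p_absent:.3f}")
for gene, t in result.tuning.items():
    print(f"{gene}: best r2 = {t.best_r2:.3f}, retained = {t.retained}")
```

prints (10,000-sample synthetic cohort, seed 1):

```
carriers:     HR 2.40 (1.95-2.94), P = 3.6e-17
non-carriers: HR 0.917, P = 0.008
AIM2: best r2 = 0.341, retained = True
IL1RAP: best r2 = 0.137, retained = True
IL6R: best r2 = 0.084, retained = True
```

The generator plants a carrier-only AIM2 effect (interaction log-HR
log 1.85) on top of a composite-CHIP hazard of log 1.18; the carrier
stratum shows the amplified per-SD hazard while the non-carrier stratum
stays near HR ≈ 0.99 (here a 2.6σ fluctuation pushes its P to 0.008 — at
α = 0.05 this seed happens not to carry the composite pair forward, while
the DNMT3A- and TET2-stratified versions of the same planted signal are
carried and FDR-significant).  AIM2's tuned r² of 0.341 recovers its
simulated cis-heritability of 0.35.

The same stages are available as a CLI:

```bash
chipscan simulate --out inputs/ --seed 1
chipscan build-scores --sumstats inputs/sumstats.tsv --ref inputs/reference.tsv \
    --genotypes inputs/genotypes.tsv --out scores/
chipscan tune --scores scores/ --genotypes inputs/validation_genotypes.tsv \
    --sumstats inputs/sumstats.tsv --ref inputs/reference.tsv \
    --expression inputs/expression.tsv --apply-genotypes inputs/genotypes.tsv \
    --out tuned/
chipscan annotate-chip --calls inputs/chip_calls.tsv \
    --samples inputs/phenotypes.tsv --out chip.tsv
chipscan scan --scores tuned/best_scores.tsv --chip chip.tsv \
    --phenotypes inputs/phenotypes.tsv --out scan/
```

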