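# Methods

## Model and assumptions

A blood-stem-cell clone that has expanded to cell fraction *f* carries the
somatic mutations of its founder cell in a fraction *f* of cells; each such
heterozygous site yields alternate reads ~ Binomial(depth, *f*/2). Clones
with *f* roughly between 0.2 and 0.5 therefore deposit many private variants
with VAF inside the indicator window [0.10, 0.25]. Three sources contaminate
that window and are handled explicitly:

1. **Germline heterozygotes.** Alt reads ~ Binomial(depth, ½); the binomial
   left tail reaches into [0.10, 0.25]. Because the distribution is
   symmetric, the expected germline count there equals the count in
   [0.75, 0.90], and the ratio of the [0.75, 0.90] to [0.35, 0.65] counts,
   r(center, depth), is a property of read sampling — not of the
   individual. r is fitted on cohort totals per (center, integer depth) and
   converts each sample's observed mid-VAF count into its expected low-VAF
   germline contamination E. The estimated somatic count is
   S = observed_low − E, summed over depths 21–60.
2. **Shared germline polymorphism.** Removed by the cohort-singleton
   restriction: only (chrom, pos, alt) keys carried by exactly one cohort
   member are counted. Allele-level keying is the default because barcode
   mutations are allele events; position-level keying is a config switch.
   Singleton status is determined before the per-variant quality filters
   (singletons are extracted first, then filtered), and after the
   SNV-only restriction.
3. **Sequencing error.** A low-VAF bump of artifacts with 1–2 alternate
   reads, removed by the alt-reads ≥ 3 filter.

S is never clamped at zero: negative values are legitimate draws of the
null distribution, and clamping would bias the null-calibration checks.
The calling decision S ≥ T uses no rounding on either side; T is the base
threshold 20 plus an additive center adjustment (+1 Vanguard, −2.2 Sanger),
with platform-specific absolute overrides (46 WGS NoPCR Nova, 32 NEB WGS)
that reflect pipelines run without base-quality recalibration. The center
and platform constants are treated as given calibration inputs; the config
accepts arbitrary centers/platforms so a user can recalibrate, but no
calibration procedure is asserted.

## Numerical choices

- **VAF-window membership is exact.** Windows are closed intervals with
  rational bounds; membership is tested as integer inequalities
  (alt·den ≥ depth·num), so sites like 3/30 = 0.10 land on the correct side
  regardless of floating-point representation. The [0.75, 0.90] window is
  treated identically to the printed "0.75–0.9".
- **Ratio fallbacks.** A (center, depth) cell with zero mid-window counts
  takes the ratio pooled over depth ± 2 within the center, then the
  center-wide pooled ratio, then the cohort-wide pooled ratio, then 0.
  Pooling keeps E finite and smooth; all stored ratios are finite and ≥ 0.
- **Exact tests.** The germline test is the exact two-sided binomial test
  of alt reads against p = ½ (potential germline iff p > 0.05, strictly, as
  printed); the vectorized form uses the closed identity
  p = min(1, 2·P(X ≤ min(k, n−k))) valid for the symmetric case. Fisher's
  variant test reports the sample odds ratio ad/bc and the two-sided p that
  sums hypergeometric tables no more probable than the observed one (the
  common exact convention; conventions differ, so this one is pinned by an
  enumeration oracle in the tests).
- **Cascade order is fixed.** In the CPLD cascade the per-key carrier count
  and potential-germline fraction are computed across all quality-passing
  carriers *before* any removal; applying the impact rule first would
  change the carrier sets and the output (a regression test pins the
  order). Every removal is attributed to exactly one step and the attrition
  log reconciles input − output.
- **CHIP recurrence filter.** The association of recurrent variants
  (≥ 15 carriers) with age and rs7705526 dosage is evaluated by Wald
  z-tests on a jointly fitted binomial GLM; a key is removed when both
  covariates have p > 0.1 or a negative estimate. Wald inference was chosen
  because statsmodels exposes it directly for the GLM family and the rule
  is a coarse threshold, not a tail-precision computation; the fit is
  isolated in one function and swappable. "minAD" is read as the minimum
  alternate-allele read count. Fit failures on degenerate keys count as
  non-association, which can only remove the variant.
- **Exclusions.** "Within 6 months after blood draw" is 183 days,
  configurable. ICD10 matching is block-prefix based with subcode
  inheritance (C91 matches C91.1) over C81–C96 and D45–D47; malformed codes
  are logged and never match. Missing hematology never excludes. The
  Bonferroni level 5.00 × 10⁻⁶ (≈ 10,000 phenotypes) is exposed as a
  constant, not recomputed.
- **Logistic fits** regress the phenotype on the CH indicator plus age,
  age², sex, optionally smoking terms; zero-variance covariates are
  dropped rather than allowed to make the design singular, and separation
  is flagged (`converged` / `note`) rather than silently reported.
  **IVW** is the closed-form no-intercept weighted least squares
  Σwβxβy / Σwβx², w = 1/se_y²; exposure standard errors do not enter.

## The synthetic cohort generator

The generator emulates exactly the structure the caller assumes: private
germline heterozygotes at Binomial(depth, ½); a shared germline pool (never
singletons); clone sites at Binomial(depth, f/2); an artifact bump with 1–2
alt reads; per-center depth laws (Poisson truncated to ≥ 1 by default,
negative binomial for overdispersion > 1, exact constant depth at
dispersion 0 for fixed-depth experiments); and configurable fractions of
records failing GQ or FILTER. Defaults, chosen once: 30,000 expected
private het sites per sample (the scale used by the calibration
experiments), error bump ~ Poisson(500), clone cell fraction ~ U(0.1, 0.6),
founder mutation count ~ Poisson(120), ages ~ U(40, 85). Clone prevalence
follows a logit-linear age curve anchored at 1% at age 40 and 50% at age
80, with odds multipliers for smoking status (×2 current, ×1.4 previous),
pack-years (+0.02 log-odds each), years since quitting (−0.03 each) and
rs7705526 dosage (log 1.28 per allele), so the association layer has known
signal to recover. Truth records count clone-origin sites whose realized
VAF lies in [0.10, 0.25] *before* quality filtering; recovery experiments
therefore switch simulated QC failures off so that estimator bias is
measured against a truth the filters have not eroded — quality-filter
behaviour is tested separately.

What the generator does **not** emulate: mapping artifacts, base-quality
error profiles, indel realignment effects, mosaic chromosomal alterations,
sex-chromosome loss, relatedness between cohort members, or subclonal
structure (each clone is one founder at one cell fraction). Passing tests
show the estimator and cascades behave correctly under the method's own
statistical model, not that the quality filters are optimal for any real
sequencing chemistry.

## Problem sizes

The calibration experiments run at: 500 samples × 30k sites (null
calibration, depth ~ Poisson(35)); 10 × 100k sites per depth at constant
depth ∈ {25, 35, 50} (ratio oracle); 400 samples × 30k sites at constant
depth 35 with half the cohort carrying clones whose founder count is set to
put ~40 true singletons in the window (spike recovery); exhaustive 2×2
tables to total 30 and binomial grids to depth 40 (exact-test oracles);
n = 20,000 for the logistic recoveries; 50 instruments for IVW. The
analysis drivers use a 250-sample, 4k-site demonstration cohort — scaled
down from the calibration conditions, with the clone-to-background contrast
unchanged.

## Known limitations

- The germline ratio is fitted on the whole cohort including CH-positive
  samples; large clones shed a negligible number of mid-window counts, but
  a cohort dominated by very large clones would bias r upward slightly.
- The indicator window misses clones with cell fraction below ~0.2 at
  typical depths; sensitivity claims are conditional on the clone placing
  mass in the window, exactly as in the underlying method.
- The CHIP panel and published CPLD list bundled under
  `src/chbarcode/resources/` are synthetic stand-ins (real gene symbols,
  constructed membership) sufficient for exercising the cascades; analyses
  of real cohorts should substitute the curated resources.
- Cox time-to-event modelling, GWAS, and meta-analysis are out of scope;
  the data model carries the fields they would need.
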