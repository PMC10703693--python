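# chbarcode

Detection of clonal hematopoiesis (CH) from cohort-scale whole-genome
sequencing variant calls using **mutational barcodes** — the private somatic
passenger mutations that every expanded blood-stem-cell clone carries —
rather than a predefined driver-gene list. The package is aimed at
statistical geneticists working with per-sample WGS variant calls plus a
cohort manifest: it provides the barcode caller, the somatic driver (CPLD /
CHIP) filter cascades, CH subtype classification, the surrounding
epidemiological statistics, and a synthetic cohort generator with known
ground truth for validating all of the above.

## The method

When a hematopoietic clone expands, its founder cell's somatic mutations
surface in blood WGS as low-VAF variants seen in exactly one cohort member.
The caller counts **indicator mutations**: cohort singletons passing quality
filters (GQ ≥ 90, FILTER ∈ {PASS, Low_QD}, 15 ≤ depth ≤ 60, alt reads ≥ 3)
with VAF in the window [0.10, 0.25]. That window is contaminated by germline
heterozygotes whose binomial read sampling strayed below 0.5, so the
germline contribution is estimated and subtracted using two facts about
heterozygous sites (alt reads ~ Binomial(depth, ½)): the VAF distribution is
symmetric, making the expected germline counts in [0.10, 0.25] and
[0.75, 0.90] equal; and the ratio

r(c, d) = (germline variants with VAF ∈ [0.75, 0.90]) / (VAF ∈ [0.35, 0.65])

is approximately constant given sequencing center *c* and depth *d*. Fitting
r on cohort totals, each sample's expected germline contamination and
estimated somatic count are

E = Σ_{d ≥ 21} r(c, d) · MID_d,    S = Σ_{d ≥ 21} LOW_d − E,

and a sample is called CH when S ≥ T, with T = 20 adjusted per center
(+1 Vanguard, −2.2 Sanger) or overridden per platform (46 WGS NoPCR Nova,
32 NEB WGS). Driver mutations are handled separately: the CPLD cascade
(depth > 10, PASS, 0.01 ≤ VAF ≤ 0.99; an exact binomial test of VAF against
0.5 marks potential germline calls; recurrent mostly-germline variants are
removed; high-impact or published-list variants are kept) and an adapted
CHIP cascade over a 73-gene panel. Barcode-positive samples with and without
a retained driver become CPLD-CH and CPLDneg-CH respectively.

## Worked example

```python
from chbarcode import SimulationConfig, simulate_cohort, call_from_tables

cohort = simulate_cohort(SimulationConfig(n_samples=250, seed=20230,
                                          n_germline_het=4000))
calls, model, attrition = call_from_tables(cohort.variants, cohort.manifest)
print(calls[calls.is_ch].head(3))
```

The numbered drivers under `analysis/` run this end to end. On the
demonstration cohort (250 samples, 63 with simulated clones) script 02
prints:

```
CH calls: 62 of 250 samples
sensitivity on clones with >= 20 true in-window singletons: 62/62 = 1.00
false positives among clone-free samples: 0
threshold by center: {'Sanger': 17.8, 'Vanguard': 21.0}
```

i.e. every clone large enough to put ≥ 20 true somatic singletons in the
indicator window is called, with no false calls among clone-free samples.
Script 03 then reduces 66 somatic driver candidates to the 30 truly spiked
ones (the recurrent germline leak-through sites are removed by the binomial
test + recurrence rule) and classifies the 62 barcode-positive samples into
30 CPLD-CH and 32 CPLDneg-CH. Script 04 applies the exclusion criteria and
recovers the planted smoking dose-response (pack-years OR 1.022 per
pack-year, years-quit OR 0.967) and a planted CH→phenotype odds ratio of
2.0 as 1.93.

## Layout

- `src/chbarcode/` — the library: `simulate` (synthetic cohorts),
  `variants` (singletons, filters, VAF-window profiles), `caller` (ratio
  model, somatic-count estimator, thresholds), `drivers` (CPLD/CHIP
  cascades, subtypes), `assoc` (exclusions, Fisher/logistic/IVW),
  `experiments` (calibration recipes), `io`, `cli`.
- `analysis/01–04` — narrative drivers writing tables under `results/`.
- `chbarcode simulate | call-barcode | associate` — CLI over the same code.

Out of scope by design: read alignment and variant calling, imputation,
GWAS engines, Cox time-to-event modelling, eQTL/proteomics layers; FILTER
status and functional annotations are consumed as given.
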