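# lohscape

Percent genomic loss-of-heterozygosity (gLOH) scoring and cohort statistics
for targeted tumor panel data, with a synthetic-data generator so the entire
pipeline is testable offline.

A tumor's percent gLOH is the fraction of the interrogated autosomal genome
in loss of heterozygosity — a segment with total copies Ci ≠ 0 and minor
allele count Mi = 0 — after excluding LOH events spanning ≥90% of a whole
chromosome or chromosome arm and regions where the inference is ambiguous.
The package implements:

* **`lohscape.synthetic_data`** — toy hg-like genome, SNP panel placement,
  planted copy-number profiles, a binomial/Poisson read-count forward model,
  cohort tables with planted alteration effects, and a survival simulator
  with a planted hazard ratio. Every generator is seed-deterministic and
  carries its ground truth.
* **`lohscape.gloh`** — the per-sample engine: median-centered log-ratio
  profile, exact penalized changepoint segmentation of the joint
  (log-ratio, folded BAF) signal, purity/ploidy grid fit with explicit
  handling of the purity–ploidy aliasing degeneracy, per-segment integer
  (Ci, Mi) assignment, the LOH call rule, arm/ambiguity exclusions, and the
  percentage formula with full length bookkeeping and QC failure states
  (low tumor content / low aneuploidy).
* **`lohscape.cohort_stats`** — distribution summary (log-normal MLE + fit
  statistic), ranked-curve inflection-point cutoff detection, and
  gLOH-high classification at fixed or derived cutoffs.
* **`lohscape.association`** — HR-pathway group assignment and contrasts
  (ANOVA, Welch tests with Monte-Carlo Dunnett or Tukey adjustment), the
  pathway-agnostic univariate screen with Bonferroni q-values and a
  prevalence filter, multivariate fits with uterine status, differential
  prevalence between uterine and non-uterine strata, and mutual
  exclusivity / co-occurrence tests.
* **`lohscape.survival`** — Kaplan–Meier estimation, log-rank testing and
  Cox regression (backed by `lifelines`), with strict-median gLOH
  dichotomization.
* **`lohscape.io` / `lohscape.cli`** — TSV/VCF/SEG readers and writers
  (1-based inclusive on disk, 0-based half-open in memory), YAML run
  configuration, and an end-to-end `report` command with a checksum
  manifest for reproducibility.

## CLI

```bash
lohscape simulate sample --seed 1 --target-gloh 20 --purity 0.7 --outdir sim/
lohscape simulate cohort --seed 1 --n-samples 1658 --outdir sim/
lohscape simulate survival --seed 1 --cohort sim/cohort.tsv --outdir sim/
lohscape gloh --snps sim/snps.tsv --ref-depth 250 --out gloh_out/
lohscape cohort --in sim/cohort.tsv --cutoffs 14,16,auto
lohscape associate --cohort sim/cohort.tsv --out assoc_out/
lohscape survive --in sim/survival.tsv
lohscape report --seed 1 --outdir report_out/   # full chain + manifest
```

## Notes and caveats

The upstream assay's segmentation algorithm, ambiguity criterion and QC
cutoffs are proprietary and unpublished; the implementations here are
documented proxies (exact DP changepoint search with a BIC-style penalty on
noise-standardized signals; an SE-scaled state-confidence margin; purity
< 0.20 and aneuploid genome fraction < 0.02 as QC thresholds). The
inflection-point cutoff depends on the smoothing bandwidth (default
n/200 ranks, reported in the output) and is not presented as a replication
of any published cutoff. Sex chromosomes are out of scope: the score is
defined over the 22 autosomes.
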