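# Methods

## The splicing index and its pipeline

The analysis assumes exon-array style data: each exon is measured by one or
more probesets, each probeset by several probes, all on a log2 intensity
scale. Processing follows the RMA pattern — quantile normalization of probe
intensities, then Tukey median polish per probeset (rows = probes,
columns = samples; the probeset signal is the overall plus the column
effect, iterated until the largest sweep median falls below 1e-6 or 10
iterations) — followed by three filters and the splicing index.

Filters, in order:

1. **Cross-hybridisation** — probesets whose `crosshyb_type` flag differs
   from 1 measure off-target signal and are removed regardless of intensity.
2. **Detection above background (DABG)** — the p-value of a probeset signal
   is its empirical exceedance against a pool of background-probe
   intensities, `p = (1 + #{b ≥ x}) / (1 + |pool|)` (add-one corrected, so
   p ∈ (0, 1]). A probeset is kept iff p < 0.05 in at least
   `ceil(0.5 × group size)` samples of at least one group. Both the 0.05 and
   the ~50% fraction are configurable: the 50% figure is a convention, not a
   sharp threshold. DABG is implemented against a supplied background pool
   rather than chip-specific antigenomic probes, which ties it naturally to
   the simulator's background model.
3. **Unique exons** — exons contained in exactly one transcript cannot vary
   between isoforms, so they carry no alternative-splicing information and
   are removed (`unique_exon_rule: single_transcript`). The alternative
   reading — exons private to one transcript of a multi-transcript gene —
   is available as `private_to_transcript`.

Filters 1 and 3 are signal-independent, so their order relative to each
other is immaterial; the audit trail records removals per filter and must
telescope exactly.

Gene intensity is the **median** of the gene's surviving exons (mean
available). The median is robust to the single-exon splice events the
simulator injects; no gene-level estimator is canonical for this statistic,
so the choice is exposed in configuration. `SI = exon − gene` on the log2
scale; single-exon genes therefore have SI ≡ 0 and are uninformative, which
is why the simulator requires at least two exons per gene.

RMA's background-correction convolution is deliberately omitted: the
simulator emits detected signals well above background, and background-level
exons are handled by the DABG filter instead.

## Differential exon usage

Paired comparisons use the within-pair difference of SI values (one-sample t
with n−1 df). Unpaired comparisons default to Welch's t; a pooled-variance
form is available. With `shrink_variance` (the default), per-exon variances
are moderated empirical-Bayes style: the hierarchical model
`s² ~ s0²·F(d, d0)` is fitted by method of moments on log variances (the
digamma/trigamma moment equations), posterior variances are
`(d0·s0² + d·s²)/(d0 + d)` and the t statistic gains d0 degrees of freedom.
When the observed spread of log variances does not exceed its sampling
spread, d0 = ∞ and every variance shrinks to the common mean — in that limit
the statistic equals the ordinary pooled-variance t, which the tests assert.
This is a documented approximation to the full REML fit; the moments
estimator recovers (d0, s0²) well at the problem sizes used here.

Both Benjamini–Hochberg step-up and Bonferroni corrections are provided
(statsmodels-backed, cross-checked in tests against a brute-force step-up
oracle). BH is the pipeline default; the report states which was used. The
tumor-vs-normal comparison is reported at adjusted p < 0.001 and the
recurrence comparison at adjusted p < 0.01 by default.

Degenerate rows — zero within-pair or within-group variance — are reported
with a `degenerate` flag and NaN p-values, never silently dropped or set
to zero.

Pavlidis template matching correlates each row against a template profile
(a named feature or an explicit vector over ≥ 4 samples); p-values come from
`t = r·√((n−2)/(1−r²))` with n−2 df. Constant rows are excluded with a
logged count. No significance threshold is canonical; both `r_min` and
`p_max` gates are supported.

## Variant filtering and association

Records are per (site, subject). The three quality criteria are QUAL ≥ 20,
total DP4 ≥ 20 and a *definitive genotype*: because the called genotype's PL
is 0 by VCF convention, a literal threshold on PL can never filter, so the
criterion is read as a genotype-quality margin — the second-smallest PL must
be ≥ 100. The literal reading (`max PL ≥ 100`) is available behind
`pl_rule="max"`. The audit counts failures per criterion (a record failing
two criteria counts under both) and the simulator truth-labels injected
failures, so the match must be exact.

Consequence summaries count **distinct** SNVs keyed by
(chrom, pos, ref, alt): a variant shared by several subjects counts once in
the class percentages, while every subject carrying it is flagged a carrier
(optionally restricted to coding classes). Fisher exact association uses
2×2 tables after dichotomising stage (Ta vs T1+, cut configurable) and grade
(low vs high); degenerate margins give p = 1 with a flag. The codon-72
polymorphism is partitioned from GT and the site's actual ref/alt bases into
CC / GC / GG (proline and arginine middle-codon bases), so the labels are
correct whichever allele the reference carries.

## Survival

Kaplan–Meier product-limit estimation and the two-group log-rank test
(χ² = (ΣO − ΣE)²/ΣV, df = 1) are thin validated wrappers over lifelines,
cross-checked in tests against hand product-limit and O/E/V tabulation
oracles. Ties follow the standard convention: events precede censorings at
equal times. No stratification or Cox modelling is included — the analyses
this package reproduces are univariable.

## qPCR

Quantification is the single-reference efficiency-corrected model:
`ratio = E_t^ΔCq_t / E_r^ΔCq_r` with `ΔCq = Cq_control − Cq_case` and
`E = 10^(−1/slope)` from the OLS fit of Cq on log10 template amount. With
both efficiencies 2 this is algebraically 2^(−ΔΔCq), asserted over random
inputs. Replicate Cq values are averaged per (sample, gene) before ratio
computation; statistics are on log2 ratios (the natural additive scale for
paired testing). Multi-reference geometric-mean normalization is not
implemented — a single reference gene (TBP) is the supported design.

## The synthetic-data generator

The generator defines the study conditions. Intensities follow an additive
log2 model:

```
probeset(e of g, s) = μ_g + δ_e + β_g·1[tumor] + γ_e·1[tumor ∧ spliced(e)]
                      + u_subject(s) + ε
```

with `μ_g ~ Uniform(6, 12)`, `δ_e ~ Normal(0, exon_sd)`,
`u ~ Normal(0, subject_sd²)`, `ε ~ Normal(0, noise_sd²)`; probe replicates
add `Normal(0, probe_noise_sd)` around the probeset signal, exercising the
median-polish summariser without a probe-affinity model. Exons flagged
undetected (a `floor(fraction × n)` subset, like all truth-flagged subsets)
are drawn from `Normal(background_mean, background_sd)` in every sample, and
a pool of ≥ 1000 background draws is emitted for DABG.

Because the model is additive in log2 units, the tumor−normal SI difference
of a spliced exon equals the injected γ exactly in the noise-free limit —
provided the gene median does not move. Two generator design choices
guarantee that anchor:

* the spliced exon of an affected gene is the **analyzable exon with the
  largest baseline offset δ** (analyzable = detected, in ≥ 2 transcripts,
  clean probesets), so adding a positive γ never changes the exon ranked at
  the gene median, and the injected effect is recoverable in principle
  rather than confounded with design-level filtering;
* only genes with **≥ 3 analyzable exons** are eligible: with two, the gene
  "median" is their mean and would absorb γ/2, biasing the sibling exon.

At most one exon per gene is spliced, keeping the truth table unambiguous.
Negative γ would break the anchoring (the shifted exon could cross the
median from above); the generator is specified for positive shifts.

Gene baselines sit well above the background mean (4.0 by default), so DABG
separates detected from undetected exons essentially perfectly. Survival
times are exponential with a multiplicative hazard for GC heterozygotes,
right-censored at a fixed horizon — log-rank is exactly calibrated under
proportional hazards, which makes power and null-uniformity checks
analytic. The codon-72 site is emitted only when polymorphic in the cohort,
with one genotype column per subject, matching variant-caller behaviour.

Default parameters: consequence-class probabilities
(missense 0.529, intron 0.235, synonymous 0.118, splice-acceptor 0.059,
frameshift 0.0295, stop-gained 0.0295), codon-72 genotype frequencies
(CC 0.647, GC 0.294, GG 0.059), SNV prevalence 0.404, recurrence rate 0.75,
stage probabilities (Ta 0.44, T1 0.43, T2 0.13) and grade probabilities
(low 0.57, high 0.43) reflect the clinical setting the package models.
Noise and effect sizes have no empirical anchor, so conventional values are
fixed once: `noise_sd 0.4`, `subject_sd 0.3`, `exon_sd 0.5`,
`probe_noise_sd 0.1`, `gene_effect 1.0`, `splice_effect 1.5` — effects
around 2- to 3-fold on the linear scale with array-like measurement noise.
All randomness derives from a single seed through named substreams
(design / cohort / intensities / variants / qPCR), so stages re-run
independently and byte-identically.

## What passing tests do and do not show

The generator draws iid Gaussian noise on an additive model with a clean
background separation. Real exon arrays have probe-affinity structure,
intensity-dependent variance, batch effects, correlated cross-hybridisation
and partial (not all-or-none) isoform switching; passing recovery tests here
validates the statistical machinery and its calibration under the stated
model, not performance on any real cohort.

A known, deliberate property worth flagging: **quantile normalization
attenuates strong one-sided differential signal**, because it forces every
sample onto a common distribution. With 10% of genes carrying a 1.5-unit
exon shift in tumors, recovered SI differences average ~8% below the
injected value (more for exons near the top of the intensity range). The
effect-recovery invariants are therefore asserted on the
normalization-free arithmetic path, while detection sensitivity and FDR are
asserted through the full pipeline, where the attenuation is immaterial.

## Numerical choices

* Quantile normalization assigns tied values the mean of the reference
  quantiles their ranks span; it is idempotent and equalises column means
  to 1e-12.
* Median polish: tolerance 1e-6 on sweep medians, 10-iteration cap;
  vectorised across probesets of equal probe count.
* DABG p-values are computed by binary search against the sorted pool; the
  add-one correction keeps them strictly positive.
* Zero-variance tests, zero-variance templates and degenerate Fisher
  margins are flagged, not errored or silently zeroed.
* The trigamma inverse for the moderation prior uses Newton iteration
  (tolerance 1e-10, 50-step cap) from the limma-style starting point
  `0.5 + 1/y`.

## Problem sizes used in the checks

The shipped test and acceptance runs use 100–500 genes × 5 exons × 40
samples for pipeline properties (20 seeds for recovery operating
characteristics), cohorts of 60–500 subjects for variant/survival
quantities, 100 replicate cohorts for log-rank power and 1000–2000 for
null-uniformity — sizes at which every asserted band is comfortably
resolved while the whole suite runs in well under a minute of simulation
time.

## Known limitations

* No CEL parsing, chip-definition handling or array QC; inputs are TSV
  matrices in the simulator's dialect.
* No GC/affinity background model, copy-number or batch structure in the
  generator; no BCG-treatment response modelling.
* The moderation hyperparameter fit is moments-based, not REML.
* Read mapping, variant calling and consequence annotation are upstream:
  the VCF and its CSQ strings are consumed, never computed.
* No enrichment analysis (GO/GSEA/ChEA) — those depend on external
  databases and web tools.
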