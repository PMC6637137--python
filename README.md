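# exonsi

Exon-level alternative-splicing analysis for paired tumor/normal cohorts,
built around the **splicing index**: for exon *e* of gene *g* in sample *s*,

```
SI(e, s) = log2 I(e, s) − log2 I(g, s)
```

the log2 ratio of normalized exon intensity to overall gene intensity, which
measures exon inclusion independently of gene-level expression changes.
Differential exon usage between groups (normal vs tumor, recurrent vs
non-recurrent) is then a per-exon test on SI values.

The package targets the kind of study design used in non-muscle-invasive
bladder cancer (NMIBC) transcriptomics: exon-array intensities for paired
normal/tumor samples, TP53-region variant calls from an mpileup-style
pipeline, qPCR validation read-outs, and recurrence-free survival follow-up.
It is aimed at computational biologists who want a tested, reusable and fully
simulatable version of that analysis rather than a one-off script stack.

## What it does

* **`exonsi.simulate`** — generates all five inputs with configurable effect
  sizes, noise levels and truth labels: an array design
  (gene → transcript → exon → probeset, with cross-hybridisation flags), a
  probe-level log2 intensity matrix plus background probe pool, a paired
  clinical cohort (recurrence, stage, grade, survival), a multi-sample VCF of
  TP53 variants with QUAL/DP4/GT:PL fields and consequence annotations, and
  replicated qPCR Cq tables.
* **`exonsi.pipeline`** — quantile normalization, Tukey median-polish probe
  summarization, detection-above-background (DABG) p-values against the
  background pool, and the three exon filters: (1) drop probesets with a
  cross-hyb flag ≠ 1, (2) keep probesets with DABG p < 0.05 in ≥ ~50% of the
  samples of at least one group, (3) drop exons unique to a single
  transcript. Then gene summaries (median of surviving exons) and the SI
  matrix, with a full filter audit trail.
* **`exonsi.diffexpr`** — paired and Welch/pooled t-tests, optional
  empirical-Bayes variance moderation (limma-style shrinkage with
  method-of-moments hyperparameters), Benjamini–Hochberg and Bonferroni
  correction, and Pavlidis template matching for correlation with
  splicing-factor expression profiles.
* **`exonsi.variants`** — VCF I/O (pysam), the three quality filters
  (QUAL ≥ 20, ΣDP4 ≥ 20, genotype-likelihood margin ≥ 100), distinct-SNV
  consequence summaries, Fisher exact association with clinical categories,
  and codon-72 (proline/arginine) genotype partitioning.
* **`exonsi.survival`** — Kaplan–Meier product-limit curves and the
  two-group log-rank test (lifelines-backed).
* **`exonsi.qpcr`** — amplification-efficiency estimation from dilution
  series and efficiency-corrected (Pfaffl) relative quantification against a
  TBP reference, with paired tumor/normal testing.
* **`exonsi.report` / CLI** — `run_all` ties every stage together and emits
  a machine-readable `summary.json` plus result tables; all randomness flows
  from one seed, so runs are byte-identical.

## Worked example

```python
import exonsi

cfg = exonsi.default_config(out_dir="out", seed=3,
                            sim={"n_genes": 60, "n_subjects": 20})
summary = exonsi.run_all(cfg)
```

or equivalently `exonsi run-all --out out --seed 3`. The human-readable
report (`out/report.txt`) for this configuration reads:

```
Splicing-index pipeline report
==============================
seed: 3   multiple-testing correction: BH

Probesets in: 356
  removed (cross-hyb flag != 1): 17
  removed (not detected above background): 16
  removed (exon unique to one transcript): 46
Probesets out: 277  (277 exons)

Tumor vs normal (paired): 7 / 277 exons significant (adjusted p < 0.001)
Recurrent vs non-recurrent: 0 / 277 exons significant (adjusted p < 0.01)

Distinct SNVs after quality filters: 15
  intron_variant: 26.7%
  missense_variant: 73.3%

Log-rank CC vs GC: chi2 = 7.2332, p = 0.007157
```

Reading it: of 356 probesets, 79 are removed by the three filters; 7 exons
change usage between paired normal and tumor samples at BH-adjusted
p < 0.001 (the simulation injected splice events into 10% of genes); 15
distinct TP53 SNVs survive the quality filters; and codon-72 heterozygous
(GC) subjects recur significantly faster than proline homozygotes (CC), as
the simulation's hazard ratio of 2 implies.

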