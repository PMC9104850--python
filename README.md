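# cgsc

Identification of embryonic-like **core glioma stem cells (c-GSCs)** in
glioblastoma single-cell expression data, and characterization of their
immune-evasive phenotype through bulk transcriptome and DNA-methylation
integration.

Glioblastoma (GBM) harbors glioma stem cells with self-renewal and
tumor-initiating capacity. A small sub-fraction of them resembles
embryonic stem cells: it co-expresses high levels of the core
pluripotency transcription factors **OCT4 (POU5F1), SOX2 and NANOG**
("OSN") and simultaneously downregulates the classical class I antigen
presentation genes **HLA-A, -B and -C** — an immune-evasion signature.
This package implements the complete computational workflow for finding
and characterizing that population, for analysts working with
single-cell matrices, bulk RNA-seq counts and EPIC-array beta-values.

## The rules at the core

* **c-GSC classification.** After removing genes with no expression in
  more than 95% of cells, a cell is a c-GSC iff its expression of each
  marker *m* ∈ {OCT4, SOX2, NANOG} is strictly above that marker's
  upper quartile Q3(*m*) computed over the pooled cohort. The eight
  high/low combinations (OSN⁻ … OSN⁺) define the categories of the HLA
  expression gradient.
* **Single-cell DEGs.** Two-sided Wilcoxon rank-sum per gene (c-GSC vs
  tumor bulk), Benjamini–Hochberg FDR; a gene is differential iff
  q < 0.05 and |log₂FC| > 0.5 (pseudocounted fold change of group
  means).
* **Bulk DEGs** (parental GBM-derived cells, GBM-DC, vs induced c-GSC
  lines, ic-GSC; 3 vs 3). Median-of-ratios size-factor normalization;
  effect = log₂ fold change of normalized means; Wald test on
  log₂-scale values; DEG iff q < 10⁻¹⁰ and |log₂FC| > 1.5.
* **Pathway agreement.** Two enrichment analyses compared over a shared
  pathway universe as a 2×2 table (a, b, c, d) with observed agreement
  p₀ = (a+d)/n, chance agreement
  p𝚎 = ((a+b)(a+c) + (c+d)(b+d))/n², **Cohen's κ** = (p₀−p𝚎)/(1−p𝚎),
  odds ratio ad/bc (Haldane 0.5 when a cell is zero) and Fisher exact p.
* **Differential methylation.** Beta-values standardized per sample
  (β̃ = β / mean sample β); a probe is a DMS iff |Δβ̃| > 1 between
  groups and the exact two-sided Wilcoxon p ≤ 0.1 (with 3 vs 3 the
  exact p has minimum 0.1, so only complete group separation passes).
* **Genomic integration.** Promoter methylation aggregates probes
  within ±1.5 kb of a transcription start site; OSN binding sites are
  the triple intersection of OCT4/SOX2/NANOG ChIP peak sets (BED,
  0-based half-open); metaprofiles average methylation in 200-bp bins
  over ±10 kb around site midpoints; the starburst table joins per-gene
  promoter Δβ̃ with expression log₂FC into quadrants (hyper-down, …).

A fully tested synthetic-data module generates all three modalities
with planted ground truth (a ~4% triple-high subpopulation with graded
HLA suppression; stemness-up/immune-down bulk shifts; promoter
hypermethylation and consensus-site hypomethylation), so every stage is
testable without external downloads.

## Worked example

`examples/01_identify_cgsc.py` simulates a 2,000-cell, 14-patient
cohort with a planted 4% triple-high subpopulation and runs the
classifier:

```
thresholds: OCT4 Q3=2, SOX2 Q3=2, NANOG Q3=2
74 c-GSCs / 2000 cells (3.70%)
14/14 patients (100.0%), per-patient 3.70% +/- 0.11 (SEM)

mean HLA expression per OSN category (falls toward OSN+ = c-GSC):
          HLA-A  HLA-B  HLA-C
category
O-S-N-    20.21  20.19  20.07
...
O+S+N+     4.57   4.55   4.39
```

The recovered pooled fraction (3.70%) sits just under the planted 4%
because a c-GSC call requires clearing all three marker quartiles
simultaneously; the HLA means fall from ~20 in triple-negative cells to
~4.5 in the triple-positive (c-GSC) category — the immune-evasion
gradient. The other examples cover the bulk reprogramming comparison
with the c-GSC centroid embedding (`02`), pathway-agreement statistics
(`03`) and the methylation arm (`04`).

## Command line

Every stage is also exposed as a thin CLI:

```sh
cgsc simulate --out bundle/ --seed 7          # synthetic input bundle
cgsc sc classify --mtx bundle/sc_counts.mtx --features bundle/sc_features.tsv \
    --barcodes bundle/sc_barcodes.tsv --meta bundle/cell_meta.tsv --out labels.tsv
cgsc meth consensus --oct4 bundle/peaks_oct4.bed --sox2 bundle/peaks_sox2.bed \
    --nanog bundle/peaks_nanog.bed --out osnbs.bed
cgsc run --synthetic --seed 7 --out run/      # all stages, summary.json
```

Exit codes: 0 success, 1 usage, 2 data error, 3 internal.

## Layout

| path | contents |
| --- | --- |
| `src/cgsc/sc.py` | gene filter, quartile thresholds, OSN classifier, cohort summary, HLA gradient, Wilcoxon DEGs |
| `src/cgsc/bulk.py` | TPM, size factors, bulk DEGs, correlation, centroid, t-SNE embedding, ORA, kappa agreement |
| `src/cgsc/methylome.py` | beta standardization, DMS, promoter windows, metaprofiles, starburst |
| `src/cgsc/intervals.py` | BED-convention interval merge/intersect, consensus binding sites |
| `src/cgsc/synthetic.py` | the three planted-truth generators |
| `src/cgsc/pipeline.py`, `src/cgsc/cli.py` | config, validation, stage runner, CLI |
| `docs/methods.md` | models, parameters, numerical choices, limitations |
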