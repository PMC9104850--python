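# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic generators do and
do not emulate.

## Single-cell c-GSC identification

**Gene filter.** A gene is retained iff its zero fraction over cells is
≤ 0.95 (default `max_zero_frac`), i.e. it is expressed in at least 5%
of cells. The comparison is inclusive at the threshold.

**Quartile rule.** Marker thresholds are the 75th percentile of each
marker over all retained cells, using the linear-interpolation quantile
at rank (n−1)·0.75 (the default quantile definition across scientific
software). Thresholds are computed on the pooled cohort by default —
all patients together — matching a pooled-cells analysis; a caller can
compute them per patient by subsetting the matrix first. A marker is
"high" iff expression is **strictly** greater than its Q3: sparse
count data put substantial mass on repeated values, and an inclusive
rule would let ties inflate the "high" set beyond 25% of cells. With
the strict rule the triple-positive fraction is bounded by the smallest
per-marker high fraction, each of which is ≤ 25%.

**Classification is monotone-invariant.** Any strictly increasing
transform applied jointly to a marker's values and its threshold leaves
the labels unchanged (covered by a property test), so normalization
choices that act monotonically per gene do not affect who is a c-GSC.

**Cohort summary.** The pooled percentage is 100·(#c-GSC)/(#cells); the
per-patient mean is reported with both SEM and SD (the across-patient
dispersion of a prevalence is conventionally quoted as mean ± SEM; both
are emitted because the convention is not universal). Patients with no
retained cells are excluded; with one patient the SEM is reported as 0
with a warning.

**Differential expression.** Per gene, a two-sided Wilcoxon rank-sum
test (normal approximation with tie correction — group sizes here are
hundreds to thousands) of c-GSC vs all remaining cells, BH-FDR over the
retained genes, effect = log₂((mean₊ + ε)/(mean₋ + ε)) with pseudocount
ε = 1 on the input scale (configurable). DEG rule: q < 0.05 and
|log₂FC| > 0.5, with "absolute fold change > 0.5" read on the log₂
scale — a raw fold-change bound of 0.5 would be asymmetric and vacuous
for upregulation. Genes constant across all cells get p = 1 and
effect 0. Input expression is used as provided; the module performs no
internal normalization (public single-cell matrices of this kind ship
already normalized).

## Bulk transcriptome

**TPM.** Per sample, count/length rates rescaled to 10⁶; columns sum to
10⁶ to within 10⁻⁶ relative.

**Size factors.** Median-of-ratios over genes with nonzero counts in
every sample (geometric-mean reference), the standard count-library
normalization. No rescaling of the factors is applied.

**Differential expression.** Effect = log₂ fold change of size-factor
normalized group means with pseudocount 1. The test statistic is a
Welch statistic on log₂(normalized + 1) with a per-group variance floor
of 10⁻⁸ (guards zero-variance genes); by default it is referred to the
**standard normal** (a Wald-style test, as negative-binomial DE tools
use for their coefficient tests). This choice is what makes the
stringent q < 10⁻¹⁰ gate attainable: a Student-t reference with 3-vs-3
replicates (≈4 df) cannot produce p-values anywhere near 10⁻¹⁰ for any
realistic effect size, so under that reference the published threshold
would never fire. The heavier null tails of the true small-sample
statistic are absorbed by the second gate, |log₂FC| > 1.5, which under
replicate noise of a deeply sequenced cell line (per-sample log₂ SD
≈ 0.3) is a > 5σ event; the joint null rate is negligible (verified by
the 50-seed null simulation). `test="welch-t"` restores the
Welch–Satterthwaite t reference for users with larger designs.

**Correlation.** Pearson on log₂(TPM+1) by default (raw option
available); constant samples yield missing off-diagonal entries.

**Centroid and embedding.** The c-GSC centroid is the per-gene mean
over all c-GSC cells, restricted to the c-GSC DEG set intersected with
the bulk gene universe. For the joint t-SNE of bulk samples plus
centroid, each point's log₂(x+1) profile is standardized across genes
**before** the per-gene z-scoring. The centroid is in single-cell
units while the samples are in TPM; without per-point standardization
the embedding geometry would encode measurement scale rather than
expression pattern. After profile standardization, proximity reflects
correlation of relative gene patterns. Exact-method t-SNE with PCA
initialization, fixed seed, perplexity = min(30, (n−1)/3) by default
and bounded above by (n−1)/3.

**Over-representation.** One-sided Fisher exact per gene set
(intersected with the universe; sets with fewer than 5 universe genes
are skipped), BH-FDR across sets, run separately on up- and
down-regulated query lists; a pathway counts as enriched for the
agreement analysis if significant in either direction.

**Agreement.** The 2×2 kappa formula is exact integer arithmetic over
the table; κ is undefined (NaN) when chance agreement is exactly 1.
The odds ratio applies the Haldane 0.5 correction iff any cell is zero.
The Fisher p is two-sided. The pathway universe is the set of GMT sets
passing the size filter against the shared gene universe; published
agreement values from other studies depend on their (unstated) universe
choice, so only the machinery — not any particular κ — is a meaningful
comparison target.

## Methylome

**Standardization.** β̃ = β / (per-sample mean β over retained probes).
Column means of β̃ are exactly 1 and the transform is idempotent. The
DMS difference rule (|Δ| > 1) is only satisfiable on this scale — raw
beta differences are bounded by 1 — which is why the rule follows
standardization.

**DMS.** Δ = mean β̃(ic-GSC) − mean β̃(GBM-DC); two-sided Wilcoxon
rank-sum p, **exact** for group sizes up to 10 per group (with 3 vs 3
the normal approximation is meaningless; the exact two-sided p lives on
{0.1, 0.2, 0.4, 0.7, 1.0}, so p ≤ 0.1 admits only complete group
separation). No multiplicity correction by default — the |Δ| > 1
filter is the primary gate and suppresses essentially all null probes —
with a BH option behind a flag.

**Promoter windows.** A probe belongs to a gene's promoter iff
|probe position − TSS| ≤ 1500 bp, strand-agnostic, inclusive at the
boundary; probes may serve multiple genes. Probe positions are 1-based;
BED inputs are 0-based half-open; distance math converts internally.
Probes flagged as overlapping SNPs or repeats are dropped before any
genomic aggregation.

**Consensus binding sites.** Maximal intervals covered by at least one
peak from each of the three factor sets: per-chromosome merge of each
set followed by pairwise sweep intersection, ((O ∩ S) ∩ N). Output is
sorted and non-overlapping; equivalence with a per-base coverage oracle
is tested on random instances.

**Metaprofile.** Anchors contribute their midpoint (floor of
(start+end)/2, the "center" convention of profile tools); every
(probe, anchor) pair within ±10 kb adds the probe's per-group mean to
bin ⌊(d + flank)/200⌋, with the right edge folded into the last bin so
the bins tile the window exactly. Empty bins are reported with missing
means, never zeros. Standardized betas are profiled by default (raw
available): group comparisons on the standardized scale are invariant
to global methylation differences between samples.

**Starburst.** Per-gene promoter summary is the mean Δ over promoter
probes (max-|Δ| behind a flag); a gene is methylation-significant iff
any promoter probe is a DMS. Genes significant on both axes get the
quadrant sign(Δ) × sign(log₂FC); everything else is "null".

## Synthetic data

The generators produce the statistical structure the analyses assume,
with planted ground truth for recovery scoring. One global seed feeds
three independent per-modality streams, so each stage is reproducible
on its own; a fixed seed yields bit-identical outputs.

**Single-cell cohort** (default 8,000 cells, 28 patients, 2,000 genes).
Negative-binomial counts parameterized by mean m and dispersion α
(variance m + αm², α = 0.1): moderately overdispersed, and the rank
test assumes nothing about it. Background gene means are log-normal
(median 0.5, σ_log = 1), giving a realistically sparse matrix. The
three markers are pinned to baseline mean 1.0 and the three HLA genes
to 20.0: pluripotency factors are lowly expressed and class I HLA
highly expressed in tumor cells, and a pinned marker scale keeps the
upper-quartile rule away from the degenerate Q3 = 0 regime that a
randomly drawn very low marker mean would produce. Planted cells
(round(n·f), f = 0.04 by default) multiply marker means by 8 and HLA
means by 0.2, and are assigned round-robin across patients so
per-patient planted fractions are deterministic to within one cell.
With these defaults the classifier recovers ≈ 3.5% of cells: each
marker clears its quartile with probability ≈ 0.95, so the triple rule
retains ≈ 0.86 of planted cells, while the background triple-high rate
(≈ 0.09³) is negligible. The generator does **not** emulate real GBM
expression programs, patient-specific composition, doublets or ambient
RNA — passing recovery tests demonstrate the classifier's behavior
under the planted model, not performance on real tumors.

**Bulk design** (3 vs 3 by default). Negative-binomial counts with
α = 0.05 around log-normal baseline means (median 150 counts): a
deeply sequenced cell-line experiment with tight replicates, which is
the regime where a q < 10⁻¹⁰ rule is meaningful at all. The OSN
markers are shifted up and the HLA genes down by the planted log₂
effect (4 by default); 50 further background genes get ±4 shifts
(half up, half down). Gene lengths are uniform 500–5000 bp.

**Methylome** (default 5,000 probes). Logit-normal betas: per-probe
baseline means drawn Beta(2, 8) (mean ≈ 0.2, emulating a
CpG-island/regulatory-biased probe panel rather than a genome-wide
average), noise σ = 0.25 on the logit scale, clipped to
[10⁻⁶, 1−10⁻⁶]. The panel's low baseline is a design property: the
standardized DMS rule divides Δβ by the sample mean beta, so a planted
promoter gain of Δβ = 0.3 standardizes to ≈ 1.4 — comfortably past the
|Δ| > 1 gate — whereas on a panel with mean 0.5 the same biological
effect could never pass. Fifty planted probes within ±1.5 kb of the
three "HLA" TSSs gain 0.3 in the ic-GSC group; probes inside the ten
1-kb consensus intervals drop to 0.3× (hypomethylation); unplanted
probes tile the consensus flanks (metaprofile baseline) and bystander
promoters (starburst nulls), and the remainder sit on a separate
chromosome as pure nulls. The three factor peak files pad the true
consensus intervals by different margins plus one private peak each, so
the triple intersection is known exactly. Array chemistry, probe-type
effects and SNP/repeat masking lists are not modeled.

## Problem sizes in tests

The unit suite runs on scaled-down conditions (600 cells / 10 patients
/ 300 genes / 1,200 probes); the acceptance suite re-runs the
recovery, gradient, DMS, bulk-error-control and determinism checks at
the full default conditions (ten 8,000-cell cohorts, twenty 5,000-probe
methylomes, fifty 3-vs-3 null bulk designs). `scripts/acceptance.py`
recomputes the same quantities from scratch at those sizes.

## Known limitations

* The bulk DE test is a two-group location test on log-normalized
  counts, not a count-model GLM; it has no shrinkage and is not meant
  to reproduce coefficient estimates of negative-binomial tools.
* The DMS rule with 3 vs 3 has exactly five attainable p-values; power
  comes almost entirely from the |Δ| > 1 gate, and no multiplicity
  control is applied by default.
* Pathway agreement depends on the chosen universe (GMT sets passing
  the size filter); κ values are not comparable across different
  universes.
* The quartile classifier is threshold-based and pooled by default;
  cohorts with strong patient-specific scaling should pre-normalize or
  compute thresholds per patient.
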