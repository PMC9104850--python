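"""Bulk transcriptome processing for the GBM-DC vs ic-GSC comparison.

Covers TPM conversion, median-of-ratios size factors, differential
expression at stringent thresholds (FDR q < 1e-10 and |log2 fold
change| > 1.5 by default), sample correlation matrices on log2(TPM+1),
the c-GSC pseudo-sample centroid, a t-SNE embedding of samples plus
centroid, Fisher-exact over-representation of GMT gene sets, and the
Cohen's-kappa / odds-ratio pathway-agreement statistic comparing two
enrichment analyses over a shared pathway universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

GROUP_DC = "GBM-DC"
GROUP_IC = "ic-GSC"


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][0]
        raise KeyError(f"no gene length for {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    rates = counts.divide(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {', '.join(map(str, zero.index))}")
    return rates.divide(totals, axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    Uses genes with nonzero counts in every sample; for each sample the
    factor is the median over those genes of count / geometric mean
    across samples.
    """
    values = counts.to_numpy(dtype=float)
    if values.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    all_nonzero = (values > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene with nonzero counts in all samples; "
            "add a pseudocount before computing size factors"
        )
    log_vals = np.log(values[all_nonzero])
    log_geomean = log_vals.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_vals - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bulk_deg(
    counts: pd.DataFrame,
    groups: pd.Series,
    q_threshold: float = 1e-10,
    lfc_threshold: float = 1.5,
    pseudocount: float = 1.0,
    test: str = "wald",
    variance_floor: float = 1e-8,
) -> pd.DataFrame:
    """Differential expression between the two bulk groups.

    Counts are scaled by median-of-ratios size factors; the effect is
    ``log2((mean_ic + eps) / (mean_dc + eps))`` on normalized counts.
    The per-gene statistic is a Welch statistic on log2(normalized +
    eps) values; with ``test="wald"`` (default) it is referred to the
    standard normal, matching the large-sample Wald testing used by
    count-model DE tools and allowing the extreme significance levels
    the DEG rule demands; ``test="welch-t"`` uses the
    Welch-Satterthwaite t reference instead.  BH-FDR across genes; a
    gene is a DEG iff q < ``q_threshold`` and |effect| >
    ``lfc_threshold``.
    """
    groups = groups.reindex(counts.columns)
    labels = set(groups.dropna().unique())
    if labels != {GROUP_DC, GROUP_IC}:
        raise ValueError(f"groups must be exactly {{{GROUP_DC!r}, {GROUP_IC!r}}}, got {labels}")
    dc = (groups == GROUP_DC).to_numpy()
    ic = (groups == GROUP_IC).to_numpy()
    if dc.sum() < 2 or ic.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    if test not in ("wald", "welch-t"):
        raise ValueError(f"unknown test {test!r}")

    norm = counts.to_numpy(dtype=float) / size_factors(counts).to_numpy()
    log_norm = np.log2(norm + pseudocount)
    x, y = log_norm[:, ic], log_norm[:, dc]
    n1, n0 = x.shape[1], y.shape[1]
    v1 = np.maximum(x.var(axis=1, ddof=1), variance_floor)
    v0 = np.maximum(y.var(axis=1, ddof=1), variance_floor)
    se = np.sqrt(v1 / n1 + v0 / n0)
    delta = x.mean(axis=1) - y.mean(axis=1)
    t = delta / se
    if test == "wald":
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        df = (v1 / n1 + v0 / n0) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # genes with no variation and no shift carry no evidence
    flat = (log_norm.max(axis=1) - log_norm.min(axis=1)) == 0
    p[flat] = 1.0

    mean_ic = norm[:, ic].mean(axis=1)
    mean_dc = norm[:, dc].mean(axis=1)
    effect = np.log2((mean_ic + pseudocount) / (mean_dc + pseudocount))
    effect[flat] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    is_deg = (q < q_threshold) & (np.abs(effect) > lfc_threshold)
    table = pd.DataFrame(
        {
            "mean_dc": mean_dc,
            "mean_ic": mean_ic,
            "log2fc": effect,
            "stat": t,
            "p": p,
            "q": q,
            "direction": np.where(effect > 0, "up", "down"),
            "is_deg": is_deg,
        },
        index=counts.index.copy(),
    )
    table.index.name = "gene"
    return table


def correlation_matrix(expr: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples, on log2(x + 1) by
    default.  Constant samples yield missing off-diagonal entries; the
    diagonal is 1."""
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    values = np.log2(expr.to_numpy(dtype=float) + 1.0) if log_transform else expr.to_numpy(dtype=float)
    frame = pd.DataFrame(values, columns=expr.columns)
    corr = frame.corr()
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def build_centroid(
    sc_matrix: pd.DataFrame,
    cgsc_flags: pd.Series | np.ndarray,
    deg_genes: pd.Index | list[str],
    bulk_genes: pd.Index | list[str] | None = None,
) -> pd.Series:
    """Pseudo-sample representing the c-GSC population: the per-gene mean
    over all c-GSC cells, restricted to the DEG gene set (intersected
    with the bulk gene universe when given)."""
    if isinstance(cgsc_flags, pd.Series):
        cgsc_flags = cgsc_flags.reindex(sc_matrix.columns).to_numpy()
    cgsc_flags = np.asarray(cgsc_flags, dtype=bool)
    if cgsc_flags.sum() < 1:
        raise ValueError("need >= 1 c-GSC cell")
    genes = pd.Index(deg_genes).intersection(sc_matrix.index)
    if bulk_genes is not None:
        genes = genes.intersection(pd.Index(bulk_genes))
    if len(genes) == 0:
        raise ValueError("empty gene intersection between DEGs and matrices")
    centroid = sc_matrix.loc[genes].iloc[:, cgsc_flags].mean(axis=1)
    centroid.name = "c-GSC centroid"
    return centroid


def embed_with_centroid(
    bulk_expr: pd.DataFrame,
    centroid: pd.Series,
    seed: int = 0,
    perplexity: float | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """t-SNE embedding of the bulk samples together with the c-GSC
    centroid pseudo-sample.

    Features are the genes shared by the bulk matrix and the centroid.
    Each point's log2(x+1) profile is standardized across genes first —
    the centroid comes from single-cell units that are not directly
    comparable with bulk TPM, and profile standardization makes the
    geometry depend on each point's relative gene pattern rather than
    its measurement scale — then features are z-scored per gene over
    the joint point set (zero-variance genes are dropped).
    Deterministic under a fixed seed.  Perplexity defaults to
    min(30, (n_points - 1) / 3) and must not exceed (n_points - 1) / 3.
    """
    genes = bulk_expr.index.intersection(centroid.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between bulk matrix and centroid")
    points = pd.concat(
        [bulk_expr.loc[genes], centroid.loc[genes].rename("centroid")], axis=1
    ).T  # points x genes
    n = points.shape[0]
    if n < 3:
        raise ValueError("need >= 3 points to embed")
    max_perp = (n - 1) / 3
    if perplexity is None:
        perplexity = min(30.0, max_perp)
    if perplexity > max_perp:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} points; "
            f"use <= {max_perp:.2f}"
        )
    values = points.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    point_sd = values.std(axis=1, keepdims=True)
    if (point_sd == 0).any():
        flat = points.index[point_sd.ravel() == 0][0]
        raise ValueError(f"point {flat!r} has a constant expression profile")
    values = (values - values.mean(axis=1, keepdims=True)) / point_sd
    sd = values.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features constant across points")
    z = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="exact",
    )
    coords = tsne.fit_transform(z)
    return pd.DataFrame(coords, index=points.index, columns=["tsne1", "tsne2"])


def ora_enrichment(
    query_genes: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
    min_set_size: int = 5,
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation of gene sets in a query.

    Gene sets are intersected with the universe and sets smaller than
    ``min_set_size`` (within the universe) are skipped.  BH-FDR across
    the tested sets.
    """
    universe = set(universe)
    query = set(query_genes) & universe
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query (after intersecting with universe)")
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if len(members) < min_set_size:
            continue
        a = len(query & members)
        b = len(members) - a
        c = len(query) - a
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, len(members), a, odds, p))
    if not rows:
        raise ValueError(f"no gene set with >= {min_set_size} genes in the universe")
    table = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "odds_ratio", "p"]
    ).set_index("set")
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


@dataclass(frozen=True)
class AgreementResult:
    """Concordance of two pathway-enrichment analyses over a shared
    universe, as a 2x2 table with Cohen's kappa, odds ratio and Fisher p.

    ``a`` counts pathways enriched in both analyses, ``b``/``c`` in one
    only, ``d`` in neither; kappa is chance-corrected agreement
    (po - pe) / (1 - pe).  The odds ratio uses a Haldane 0.5 correction
    iff any cell is zero.
    """

    a: int
    b: int
    c: int
    d: int
    po: float
    pe: float
    kappa: float
    odds_ratio: float
    fisher_p: float

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def kappa_from_counts(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """(po, pe, kappa) of a 2x2 agreement table; kappa is NaN when the
    marginals make chance agreement exactly 1."""
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty 2x2 table")
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    kappa = np.nan if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return po, pe, kappa


def pathway_agreement(
    enriched_a: set[str] | list[str],
    enriched_b: set[str] | list[str],
    universe: set[str] | list[str],
) -> AgreementResult:
    """Agreement between two sets of enriched pathways over a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty pathway universe")
    set_a = set(enriched_a) & universe
    set_b = set(enriched_b) & universe
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    po, pe, kappa = kappa_from_counts(a, b, c, d)
    if min(a, b, c, d) == 0:
        ah, bh, ch, dh = (x + 0.5 for x in (a, b, c, d))
    else:
        ah, bh, ch, dh = float(a), float(b), float(c), float(d)
    odds = (ah * dh) / (bh * ch)
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return AgreementResult(
        a=a, b=b, c=c, d=d, po=po, pe=pe, kappa=float(kappa),
        odds_ratio=float(odds), fisher_p=float(fisher_p),
    )
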