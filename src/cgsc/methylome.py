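"""DNA-methylation analyses: beta standardization, differential
methylation, promoter-window aggregation, metaprofiles around consensus
OSN binding sites, and the expression x methylation starburst join.

Beta values are methylation fractions in [0, 1] on EPIC-like probes.
Differential methylation is called on the standardized scale (each
probe's beta divided by its sample's mean beta), where the "difference
greater than 1" rule is meaningful; the raw beta scale, whose pairwise
differences never exceed 1, cannot satisfy it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

GROUP_DC = "GBM-DC"
GROUP_IC = "ic-GSC"


def standardize_beta(beta: pd.DataFrame) -> pd.DataFrame:
    """Divide each probe's beta by the per-sample mean beta.

    Column means of the result are exactly 1; the transform is
    idempotent up to that rescaling (standardizing twice equals once).
    """
    values = beta.to_numpy(dtype=float)
    col_means = values.mean(axis=0)
    if (col_means <= 0).any():
        bad = beta.columns[col_means <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive mean beta")
    return beta / col_means


def call_dms(
    std: pd.DataFrame,
    groups: pd.Series,
    delta_threshold: float = 1.0,
    p_threshold: float = 0.1,
    exact_max_n: int = 10,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Differentially methylated sites on standardized beta values.

    Per probe: delta = mean(ic-GSC) - mean(GBM-DC) and a two-sided
    Wilcoxon rank-sum p-value — exact when both groups have at most
    ``exact_max_n`` samples (with 3 vs 3 the exact two-sided p has a
    10-point support with minimum 0.1), normal approximation with tie
    correction otherwise.  A probe is a DMS iff |delta| >
    ``delta_threshold`` and p <= ``p_threshold``; no multiplicity
    correction is applied by default (the strict delta filter is the
    primary gate), but ``bh_correct=True`` applies BH and gates on q.
    """
    groups = groups.reindex(std.columns)
    dc = (groups == GROUP_DC).to_numpy()
    ic = (groups == GROUP_IC).to_numpy()
    if dc.sum() < 2 or ic.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    values = std.to_numpy(dtype=float)
    x, y = values[:, ic], values[:, dc]
    method = "exact" if max(x.shape[1], y.shape[1]) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(x, y, axis=-1, method=method)
    p = np.asarray(res.pvalue, dtype=float)
    constant = values.max(axis=1) == values.min(axis=1)
    p[constant] = 1.0
    delta = x.mean(axis=1) - y.mean(axis=1)
    gate_p = multipletests(p, method="fdr_bh")[1] if bh_correct else p
    is_dms = (np.abs(delta) > delta_threshold) & (gate_p <= p_threshold)
    table = pd.DataFrame(
        {
            "mean_dc": y.mean(axis=1),
            "mean_ic": x.mean(axis=1),
            "delta": delta,
            "p": p,
            "sign": np.where(delta > 0, "hyper", "hypo"),
            "is_dms": is_dms,
        },
        index=std.index.copy(),
    )
    if bh_correct:
        table.insert(4, "q", gate_p)
    table.index.name = "probe"
    return table


def drop_masked_probes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Remove probes flagged as overlapping SNPs or repetitive elements."""
    if "masked" not in annotation.columns:
        return annotation
    return annotation.loc[~annotation["masked"].astype(bool)]


def promoter_probes(
    annotation: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 1500,
) -> dict[str, list[str]]:
    """Map each gene to the probes within +/-``window`` bp of its TSS.

    Strand-agnostic and inclusive at the boundary: a probe at exactly
    TSS +/- window is assigned.  Probes may map to multiple genes; genes
    without probes map to an empty list.  Positions are 1-based in both
    inputs, so distances are direct differences.
    """
    annotation = drop_masked_probes(annotation)
    out: dict[str, list[str]] = {}
    by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in annotation.groupby("chrom")
    }
    for row in tss.itertuples(index=False):
        gene = row.gene
        out.setdefault(gene, [])
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, row.pos - window, side="left")
        hi = np.searchsorted(pos, row.pos + window, side="right")
        out[gene].extend(grp["probe"].to_numpy()[lo:hi])
    return out


def metaprofile(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    anchors: list[GenomicInterval],
    groups: pd.Series,
    flank: int = 10000,
    bin_width: int = 200,
) -> pd.DataFrame:
    """Mean methylation per distance bin around anchor midpoints, per group.

    Every (probe, anchor) pair with signed distance d = probe_pos0 -
    anchor_midpoint in [-flank, +flank] contributes the probe's
    per-group mean beta to bin floor((d + flank) / bin_width) (the
    right edge is folded into the last bin, so the bins tile the window
    exactly).  Probe positions are converted from 1-based to 0-based
    before the distance computation.  Returns a tidy frame with one row
    per (bin, group): bin start/center offsets, group, mean and the
    number of contributing (probe, anchor) pairs; empty bins are
    reported with a missing mean.
    """
    if not anchors:
        raise ValueError("no anchor intervals")
    annotation = drop_masked_probes(annotation)
    n_bins = (2 * flank) // bin_width
    group_names = [GROUP_DC, GROUP_IC]
    group_means = {
        g: beta.loc[:, groups.reindex(beta.columns).to_numpy() == g].mean(axis=1)
        for g in group_names
    }
    by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in annotation.groupby("chrom")
    }
    sums = {g: np.zeros(n_bins) for g in group_names}
    counts = np.zeros(n_bins, dtype=int)
    for anchor in anchors:
        grp = by_chrom.get(anchor.chrom)
        if grp is None:
            continue
        pos0 = grp["pos"].to_numpy() - 1
        mid = anchor.midpoint
        lo = np.searchsorted(pos0, mid - flank, side="left")
        hi = np.searchsorted(pos0, mid + flank, side="right")
        if lo == hi:
            continue
        d = pos0[lo:hi] - mid
        bins = np.minimum((d + flank) // bin_width, n_bins - 1).astype(int)
        ids = grp["probe"].to_numpy()[lo:hi]
        np.add.at(counts, bins, 1)
        for g in group_names:
            vals = group_means[g].reindex(ids).to_numpy()
            np.add.at(sums[g], bins, vals)
    if counts.sum() == 0:
        warnings.warn("no probes fall within the anchor windows")
    rows = []
    for b in range(n_bins):
        start = b * bin_width - flank
        center = start + bin_width / 2
        for g in group_names:
            mean = sums[g][b] / counts[b] if counts[b] else np.nan
            rows.append((start, center, g, mean, int(counts[b])))
    return pd.DataFrame(
        rows, columns=["bin_start", "bin_center", "group", "mean", "n"]
    )


def promoter_dms_summary(
    dms: pd.DataFrame,
    promoter_map: dict[str, list[str]],
    how: str = "mean",
) -> pd.DataFrame:
    """Per-gene promoter methylation summary from a DMS table.

    ``how="mean"`` (default) reports the mean delta over the gene's
    promoter probes; ``how="max"`` the delta of largest magnitude.  A
    gene is methylation-significant iff any of its promoter probes is a
    DMS.  Genes without probes are omitted.
    """
    if how not in ("mean", "max"):
        raise ValueError(f"unknown summary {how!r}")
    rows = []
    for gene, probes in promoter_map.items():
        probes = [p for p in probes if p in dms.index]
        if not probes:
            continue
        sub = dms.loc[probes]
        if how == "mean":
            delta = float(sub["delta"].mean())
        else:
            delta = float(sub["delta"].iloc[np.argmax(np.abs(sub["delta"].to_numpy()))])
        rows.append((gene, delta, bool(sub["is_dms"].any()), len(probes)))
    return pd.DataFrame(
        rows, columns=["gene", "delta", "significant", "n_probes"]
    ).set_index("gene")


def starburst(deg: pd.DataFrame, promoter_summary: pd.DataFrame) -> pd.DataFrame:
    """Join per-gene expression change with promoter methylation change.

    Genes significant on both axes (a DEG with a significant promoter)
    get a quadrant from the sign pair — ``hyper-up``, ``hyper-down``,
    ``hypo-up`` or ``hypo-down`` (methylation sign first); everything
    else is ``null``.
    """
    genes = deg.index.intersection(promoter_summary.index)
    if len(genes) == 0:
        raise ValueError("no genes shared by the DEG table and promoter summary")
    expr = deg.loc[genes]
    meth = promoter_summary.loc[genes]
    meth_sign = np.where(meth["delta"] > 0, "hyper", "hypo")
    expr_sign = np.where(expr["log2fc"] > 0, "up", "down")
    significant = expr["is_deg"].to_numpy() & meth["significant"].to_numpy()
    quadrant = np.where(
        significant,
        np.char.add(np.char.add(meth_sign.astype(str), "-"), expr_sign.astype(str)),
        "null",
    )
    out = pd.DataFrame(
        {
            "log2fc": expr["log2fc"],
            "meth_delta": meth["delta"],
            "is_deg": expr["is_deg"],
            "meth_significant": meth["significant"],
            "quadrant": quadrant,
        },
        index=genes,
    )
    out.index.name = "gene"
    return out
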