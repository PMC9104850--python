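"""End-to-end orchestration: configuration, input validation, the
sc -> bulk -> methylome stage runner, and synthetic-bundle export.

A run executes whichever stages have their inputs configured, writes
per-stage TSV outputs plus a machine-readable ``summary.json`` into a
run directory, and is byte-reproducible for a fixed config and seed
(output headers carry the tool version and a config hash, never a
timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, bulk, intervals, io, methylome, sc
from .synthetic import SyntheticConfig, simulate_bulk, simulate_methylome, simulate_sc_cohort

log = logging.getLogger("cgsc")


@dataclass
class PipelineConfig:
    """Paths to the stage inputs plus every analysis threshold.

    Threshold defaults are the pipeline's canonical rules: gene filter
    at 95% zero fraction; single-cell DEGs at q < 0.05 and |log2FC| >
    0.5; bulk DEGs at q < 1e-10 and |log2FC| > 1.5; DMS at
    |standardized delta| > 1 and Wilcoxon p <= 0.1; promoter window
    +/-1.5 kb; metaprofile flank +/-10 kb.
    """

    # single-cell stage
    sc_matrix: str | None = None
    sc_mtx: str | None = None
    sc_features: str | None = None
    sc_barcodes: str | None = None
    cell_meta: str | None = None
    markers: list[str] = field(default_factory=lambda: list(sc.DEFAULT_MARKERS))
    hla_genes: list[str] = field(default_factory=lambda: list(sc.DEFAULT_HLA_GENES))
    # bulk stage
    bulk_counts: str | None = None
    bulk_design: str | None = None
    gene_lengths: str | None = None
    gene_sets: str | None = None
    # methylome stage
    beta_matrix: str | None = None
    meth_design: str | None = None
    probe_annotation: str | None = None
    peaks_oct4: str | None = None
    peaks_sox2: str | None = None
    peaks_nanog: str | None = None
    tss: str | None = None
    # thresholds
    max_zero_frac: float = 0.95
    sc_q: float = 0.05
    sc_lfc: float = 0.5
    bulk_q: float = 1e-10
    bulk_lfc: float = 1.5
    dms_delta: float = 1.0
    dms_p: float = 0.1
    promoter_window: int = 1500
    flank: int = 10000
    bin_width: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return f"cgsc v{__version__} config={config.config_hash()}"


def write_synthetic_bundle(
    config: SyntheticConfig, outdir: str | Path
) -> PipelineConfig:
    """Generate all three synthetic modalities and write them as the
    plain-text bundle the pipeline consumes; returns a PipelineConfig
    pointing at the files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = simulate_sc_cohort(config)
    io.write_mtx(cohort.counts, outdir / "sc_counts.mtx",
                 outdir / "sc_features.tsv", outdir / "sc_barcodes.tsv")
    meta = pd.DataFrame(
        {"patient": cohort.patient_of, "planted": cohort.planted}
    )
    meta.to_csv(outdir / "cell_meta.tsv", sep="\t")

    bulk_sim = simulate_bulk(config)
    io.write_matrix_tsv(bulk_sim.counts, outdir / "bulk_counts.tsv")
    bulk_sim.groups.rename("group").rename_axis("sample").reset_index().to_csv(
        outdir / "bulk_design.tsv", sep="\t", index=False
    )
    bulk_sim.gene_lengths.rename_axis("gene").reset_index().to_csv(
        outdir / "gene_lengths.tsv", sep="\t", index=False
    )
    bulk_sim.true_log2_effect.rename_axis("gene").reset_index().to_csv(
        outdir / "bulk_truth.tsv", sep="\t", index=False
    )

    meth = simulate_methylome(config)
    io.write_matrix_tsv(meth.beta, outdir / "beta.tsv")
    meth.groups.rename("group").rename_axis("sample").reset_index().to_csv(
        outdir / "meth_design.tsv", sep="\t", index=False
    )
    meth.annotation.to_csv(outdir / "probe_annotation.tsv", sep="\t", index=False)
    meth.tss.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    for factor, fname in (("OCT4", "peaks_oct4.bed"), ("SOX2", "peaks_sox2.bed"),
                          ("NANOG", "peaks_nanog.bed")):
        io.write_bed(meth.peaks[factor], outdir / fname)
    pd.DataFrame(
        {"planted_hyper": meth.planted_hyper, "planted_hypo": meth.planted_hypo}
    ).to_csv(outdir / "meth_truth.tsv", sep="\t")

    return PipelineConfig(
        sc_mtx=str(outdir / "sc_counts.mtx"),
        sc_features=str(outdir / "sc_features.tsv"),
        sc_barcodes=str(outdir / "sc_barcodes.tsv"),
        cell_meta=str(outdir / "cell_meta.tsv"),
        bulk_counts=str(outdir / "bulk_counts.tsv"),
        bulk_design=str(outdir / "bulk_design.tsv"),
        gene_lengths=str(outdir / "gene_lengths.tsv"),
        beta_matrix=str(outdir / "beta.tsv"),
        meth_design=str(outdir / "meth_design.tsv"),
        probe_annotation=str(outdir / "probe_annotation.tsv"),
        peaks_oct4=str(outdir / "peaks_oct4.bed"),
        peaks_sox2=str(outdir / "peaks_sox2.bed"),
        peaks_nanog=str(outdir / "peaks_nanog.bed"),
        tss=str(outdir / "tss.tsv"),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# validation


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Per-file format and consistency checks; returns a list of
    human-readable error strings (empty when everything validates)."""
    errors: list[str] = []

    def check(path: str | None, loader, what: str):
        if path is None:
            return None
        if not Path(path).exists():
            errors.append(f"{what}: file not found: {path}")
            return None
        try:
            return loader(path)
        except Exception as exc:
            errors.append(f"{what}: {exc}")
            return None

    if config.sc_matrix:
        m = check(config.sc_matrix, io.read_matrix_tsv, "sc matrix")
        if m is not None:
            missing = [g for g in config.markers if g not in m.index]
            if missing:
                errors.append(f"sc matrix: missing marker gene(s) {', '.join(missing)}")
    check(config.cell_meta, io.read_cell_meta, "cell metadata")
    check(config.bulk_counts, io.read_matrix_tsv, "bulk counts")
    check(config.bulk_design, io.read_design, "bulk design")
    check(config.gene_lengths, io.read_gene_lengths, "gene lengths")
    beta = check(config.beta_matrix, io.read_matrix_tsv, "beta matrix")
    if beta is not None:
        values = beta.to_numpy()
        bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = [int(x[0]) for x in bad.nonzero()]
            errors.append(
                f"beta matrix: value {values[i, j]:g} out of [0, 1] at "
                f"probe {beta.index[i]!r}, sample {beta.columns[j]!r}"
            )
    check(config.probe_annotation, io.read_probe_annotation, "probe annotation")
    check(config.tss, io.read_tss, "TSS table")
    for path, what in ((config.peaks_oct4, "OCT4 peaks"),
                       (config.peaks_sox2, "SOX2 peaks"),
                       (config.peaks_nanog, "NANOG peaks")):
        check(path, io.read_bed, what)
    check(config.gene_sets, io.read_gmt, "gene sets")
    return errors


# ---------------------------------------------------------------------------
# stage runner


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage whose inputs are configured; write stage outputs
    and ``summary.json`` under ``outdir`` and return the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    sc_labels = None
    sc_matrix = None
    sc_deg_table = None
    if config.sc_matrix or config.sc_mtx:
        log.info("stage sc: classify c-GSCs")
        if config.sc_mtx:
            sc_matrix = io.read_mtx(config.sc_mtx, config.sc_features, config.sc_barcodes)
        else:
            sc_matrix = io.read_matrix_tsv(config.sc_matrix)
        patient_of = io.read_cell_meta(config.cell_meta)
        sc_matrix = sc.filter_genes(sc_matrix, config.max_zero_frac)
        thresholds = sc.marker_thresholds(sc_matrix, tuple(config.markers))
        sc_labels = sc.classify_osn(sc_matrix, thresholds, tuple(config.markers))
        summ = sc.cohort_summary(sc_labels, patient_of)
        labels_out = sc_labels[["category", "is_cgsc"]]
        io.write_matrix_tsv(labels_out, outdir / "sc_labels.tsv", header)
        gradient = sc.hla_gradient(sc_matrix, sc_labels, tuple(config.hla_genes))
        io.write_matrix_tsv(gradient.means, outdir / "sc_hla_gradient.tsv", header)
        sc_deg_table = sc.wilcoxon_deg(
            sc_matrix, sc_labels["is_cgsc"], config.sc_q, config.sc_lfc
        )
        io.write_matrix_tsv(sc_deg_table, outdir / "sc_deg.tsv", header)
        summary["stages"]["sc"] = {
            "n_cells": int(sc_matrix.shape[1]),
            "n_genes_retained": int(sc_matrix.shape[0]),
            "pooled_cgsc_fraction_pct": round(summ.pooled_fraction_pct, 4),
            "mean_patient_fraction_pct": round(summ.mean_pct, 4),
            "sem_patient_fraction_pct": round(summ.sem_pct, 4),
            "n_patients": summ.n_patients,
            "n_patients_with_cgsc": summ.n_patients_with_cgsc,
            "n_deg": int(sc_deg_table["is_deg"].sum()),
        }
    else:
        summary["stages"]["sc"] = {"skipped": "no single-cell matrix configured"}
        log.info("stage sc skipped: no input")

    bulk_deg_table = None
    if config.bulk_counts:
        log.info("stage bulk: TPM, DEG, correlation")
        counts = io.read_matrix_tsv(config.bulk_counts)
        groups = io.read_design(config.bulk_design)
        tpm = None
        if config.gene_lengths:
            lengths = io.read_gene_lengths(config.gene_lengths)
            tpm = bulk.counts_to_tpm(counts, lengths)
            io.write_matrix_tsv(tpm, outdir / "bulk_tpm.tsv", header)
        bulk_deg_table = bulk.bulk_deg(
            counts, groups, config.bulk_q, config.bulk_lfc
        )
        io.write_matrix_tsv(bulk_deg_table, outdir / "bulk_deg.tsv", header)
        corr = bulk.correlation_matrix(tpm if tpm is not None else counts)
        io.write_matrix_tsv(corr, outdir / "bulk_correlation.tsv", header)
        stage: dict = {
            "n_genes": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
            "n_deg": int(bulk_deg_table["is_deg"].sum()),
        }
        if sc_matrix is not None and sc_deg_table is not None:
            deg_genes = sc_deg_table.index[sc_deg_table["is_deg"]]
            shared = deg_genes.intersection(counts.index)
            if len(shared) and sc_labels["is_cgsc"].any():
                centroid = bulk.build_centroid(
                    sc_matrix, sc_labels["is_cgsc"], deg_genes, counts.index
                )
                embedding = bulk.embed_with_centroid(
                    (tpm if tpm is not None else counts).loc[shared],
                    centroid, seed=config.seed,
                )
                io.write_matrix_tsv(embedding, outdir / "bulk_tsne.tsv", header)
                stage["embedded_points"] = int(embedding.shape[0])
        summary["stages"]["bulk"] = stage
    else:
        summary["stages"]["bulk"] = {"skipped": "no bulk counts configured"}
        log.info("stage bulk skipped: no input")

    if config.gene_sets and sc_deg_table is not None and bulk_deg_table is not None:
        log.info("stage agreement: pathway concordance")
        gene_sets = io.read_gmt(config.gene_sets)
        universe = set(sc_deg_table.index) & set(bulk_deg_table.index)
        enriched = {}
        for name, table in (("sc", sc_deg_table), ("bulk", bulk_deg_table)):
            hits: set[str] = set()
            for direction in ("up", "down"):
                query = set(
                    table.index[table["is_deg"] & (table["direction"] == direction)]
                ) & universe
                if not query:
                    continue
                ora = bulk.ora_enrichment(query, gene_sets, universe)
                hits |= set(ora.index[ora["q"] < 0.05])
            enriched[name] = hits
        pathway_universe = {
            name for name, members in gene_sets.items()
            if len(set(members) & universe) >= 5
        }
        agreement = bulk.pathway_agreement(
            enriched["sc"], enriched["bulk"], pathway_universe
        )
        summary["stages"]["agreement"] = {
            "a": agreement.a, "b": agreement.b, "c": agreement.c, "d": agreement.d,
            "kappa": round(agreement.kappa, 6),
            "odds_ratio": round(agreement.odds_ratio, 4),
            "fisher_p": agreement.fisher_p,
        }

    if config.beta_matrix:
        log.info("stage methylome: DMS, promoters, consensus, metaprofile")
        beta = io.read_matrix_tsv(config.beta_matrix)
        groups = io.read_design(config.meth_design or config.bulk_design)
        std = methylome.standardize_beta(beta)
        dms = methylome.call_dms(std, groups, config.dms_delta, config.dms_p)
        io.write_matrix_tsv(dms, outdir / "dms.tsv", header)
        stage = {
            "n_probes": int(beta.shape[0]),
            "n_dms": int(dms["is_dms"].sum()),
        }
        annotation = tss = None
        if config.probe_annotation and config.tss:
            annotation = io.read_probe_annotation(config.probe_annotation)
            tss = io.read_tss(config.tss)
            promoter_map = methylome.promoter_probes(
                annotation, tss, config.promoter_window
            )
            promoter_summary = methylome.promoter_dms_summary(dms, promoter_map)
            io.write_matrix_tsv(
                promoter_summary, outdir / "promoter_methylation.tsv", header
            )
            stage["n_genes_with_promoter_probes"] = int(promoter_summary.shape[0])
            if bulk_deg_table is not None:
                star = methylome.starburst(bulk_deg_table, promoter_summary)
                io.write_matrix_tsv(star, outdir / "starburst.tsv", header)
                stage["starburst_quadrants"] = (
                    star["quadrant"].value_counts().to_dict()
                )
        if config.peaks_oct4 and config.peaks_sox2 and config.peaks_nanog:
            consensus = intervals.consensus_binding_sites(
                io.read_bed(config.peaks_oct4),
                io.read_bed(config.peaks_sox2),
                io.read_bed(config.peaks_nanog),
            )
            io.write_bed(consensus, outdir / "consensus_osnbs.bed")
            stage["n_consensus_sites"] = len(consensus)
            if annotation is not None and consensus:
                profile = methylome.metaprofile(
                    std, annotation, consensus, groups,
                    config.flank, config.bin_width,
                )
                profile.to_csv(outdir / "metaprofile.tsv", sep="\t", index=False)
        summary["stages"]["methylome"] = stage
    else:
        summary["stages"]["methylome"] = {"skipped": "no beta matrix configured"}
        log.info("stage methylome skipped: no input")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
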