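"""Synthetic data with the statistical structure the c-GSC pipeline assumes.

Three generators cover the three data modalities the pipeline consumes:

* ``simulate_sc_cohort`` — a negative-binomial scRNA-seq cohort
  (~8,000 cells across ~28 patients by default) with a planted
  triple-high OCT4/SOX2/NANOG subpopulation showing graded HLA-A/B/C
  downregulation;
* ``simulate_bulk`` — a 3-vs-3 bulk RNA-seq count design (GBM-derived
  cells vs induced c-GSC lines) with planted log2 expression shifts;
* ``simulate_methylome`` — an EPIC-like beta-value matrix with planted
  promoter hypermethylation at HLA transcription start sites and
  hypomethylation inside triple-consensus OSN binding intervals, plus
  the BED peak sets and TSS table needed downstream.

Every generator returns ground-truth planted flags so downstream callers
can be scored for recovery.  One global seed feeds independent
per-modality random streams, so each stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .sc import DEFAULT_HLA_GENES, DEFAULT_MARKERS


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort, bulk design and methylome.

    Defaults emulate the study conditions the pipeline targets: a pooled
    cohort of 8,000 cells from 28 patients with ~4% planted triple-high
    cells, strong (8x) marker induction and strong (0.2x) HLA class I
    suppression in the planted cells, and a 3-vs-3 bulk design.
    """

    n_cells: int = 8000
    n_patients: int = 28
    n_genes: int = 2000
    planted_fraction: float = 0.04
    marker_effect: float = 8.0
    hla_effect: float = 0.2
    nb_dispersion: float = 0.1
    seed: int = 0
    n_probes: int = 5000
    n_bulk_reps: int = 3
    beta_noise_sd: float = 0.25
    # bulk planted differential expression
    n_deg_genes: int = 50
    bulk_log2_effect: float = 4.0
    # methylome planted effects
    n_dms_probes: int = 50
    dms_delta_beta: float = 0.3
    # baseline means for the named marker / HLA genes (sc counts)
    marker_baseline_mean: float = 1.0
    hla_baseline_mean: float = 20.0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_patients", "n_genes", "n_probes", "n_bulk_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.planted_fraction < 1:
            raise ValueError("planted_fraction must be in (0, 1)")
        if not 0 < self.hla_effect <= 1:
            raise ValueError("hla_effect must be in (0, 1]")
        if self.marker_effect <= 0:
            raise ValueError("marker_effect must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.beta_noise_sd < 0:
            raise ValueError("beta_noise_sd must be >= 0")

    def _streams(self) -> tuple[np.random.Generator, ...]:
        sc, bulk, meth = np.random.SeedSequence(self.seed).spawn(3)
        return (
            np.random.default_rng(sc),
            np.random.default_rng(bulk),
            np.random.default_rng(meth),
        )


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws parameterized by mean m and dispersion a
    (variance m + a m^2)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# single-cell cohort


@dataclass(frozen=True)
class ScCohort:
    counts: pd.DataFrame          # genes x cells
    patient_of: pd.Series         # cell -> patient label
    planted: pd.Series = field(repr=False)  # cell -> bool ground truth


def simulate_sc_cohort(config: SyntheticConfig) -> ScCohort:
    """Simulate a pooled scRNA-seq cohort with a planted triple-high
    OSN subpopulation.

    Exactly ``round(n_cells * planted_fraction)`` cells are planted;
    cells are assigned to patients round-robin, so planted cells spread
    evenly across patients (per-patient counts differ by at most one).
    Planted cells draw the three OSN markers with mean multiplied by
    ``marker_effect`` and the three HLA class I genes with mean
    multiplied by ``hla_effect``.  Background gene means are log-normal;
    the named marker and HLA genes get fixed baseline means so the
    upper-quartile classification rule operates on a stable scale.
    """
    rng, _, _ = config._streams()
    n_genes, n_cells = config.n_genes, config.n_cells
    special = list(DEFAULT_MARKERS) + list(DEFAULT_HLA_GENES)
    if n_genes < len(special):
        raise ValueError(f"n_genes must be >= {len(special)}")
    n_bg = n_genes - len(special)
    genes = special + [f"gene{i:05d}" for i in range(n_bg)]

    base_mean = np.empty(n_genes)
    base_mean[:3] = config.marker_baseline_mean
    base_mean[3:6] = config.hla_baseline_mean
    base_mean[6:] = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=n_bg)

    cells = [f"cell{i:05d}" for i in range(n_cells)]
    patients = np.array(
        [f"patient{i % config.n_patients + 1:02d}" for i in range(n_cells)]
    )
    n_planted = int(round(n_cells * config.planted_fraction))
    planted = np.zeros(n_cells, dtype=bool)
    planted[:n_planted] = True  # round-robin patient labels => even spread

    mean = np.tile(base_mean[:, None], (1, n_cells))
    mean[:3, planted] *= config.marker_effect
    mean[3:6, planted] *= config.hla_effect
    counts = _nb_counts(rng, mean, config.nb_dispersion)

    counts = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(cells, name="cell"))
    return ScCohort(
        counts=counts,
        patient_of=pd.Series(patients, index=counts.columns, name="patient"),
        planted=pd.Series(planted, index=counts.columns, name="planted"),
    )


# ---------------------------------------------------------------------------
# bulk 3-vs-3 design

GROUP_DC = "GBM-DC"
GROUP_IC = "ic-GSC"


@dataclass(frozen=True)
class BulkSim:
    counts: pd.DataFrame          # genes x samples
    groups: pd.Series             # sample -> group label
    gene_lengths: pd.Series       # gene -> length (bp)
    true_log2_effect: pd.Series = field(repr=False)  # planted per-gene shift


def simulate_bulk(config: SyntheticConfig) -> BulkSim:
    """Simulate two bulk groups with ``n_bulk_reps`` replicates each.

    ``n_deg_genes`` background genes are shifted in the ic-GSC group by
    ``bulk_log2_effect`` on the log2 scale (half up, half down); in
    addition the three OSN markers are shifted up and the three HLA
    class I genes down by the same magnitude, mirroring the stemness-up
    / immune-down reprogramming signature.  The per-gene planted shift
    is returned as ground truth (0 elsewhere).  Baseline gene means are
    log-normal around ~150 counts, i.e. a deeply sequenced cell-line
    library where biological replicates are tight.
    """
    if config.n_bulk_reps < 2:
        raise ValueError("n_bulk_reps must be >= 2")
    _, rng, _ = config._streams()
    n_genes = config.n_genes
    special = list(DEFAULT_MARKERS) + list(DEFAULT_HLA_GENES)
    if n_genes < len(special):
        raise ValueError(f"n_genes must be >= {len(special)}")
    genes = special + [f"gene{i:05d}" for i in range(n_genes - len(special))]
    samples = [f"{GROUP_DC}{i + 1}" for i in range(config.n_bulk_reps)] + [
        f"{GROUP_IC}{i + 1}" for i in range(config.n_bulk_reps)
    ]
    groups = pd.Series(
        [GROUP_DC] * config.n_bulk_reps + [GROUP_IC] * config.n_bulk_reps,
        index=pd.Index(samples, name="sample"),
        name="group",
    )

    base_mean = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=n_genes)
    effect = np.zeros(n_genes)
    effect[:3] = config.bulk_log2_effect     # OSN markers up in ic-GSC
    effect[3:6] = -config.bulk_log2_effect   # HLA class I down in ic-GSC
    n_deg = min(config.n_deg_genes, n_genes - len(special))
    deg_idx = len(special) + rng.choice(
        n_genes - len(special), size=n_deg, replace=False
    )
    half = n_deg // 2
    effect[deg_idx[:half]] = config.bulk_log2_effect
    effect[deg_idx[half:]] = -config.bulk_log2_effect

    mean = np.tile(base_mean[:, None], (1, 2 * config.n_bulk_reps))
    mean[:, config.n_bulk_reps:] *= 2.0 ** effect[:, None]
    counts = _nb_counts(rng, mean, 0.05)

    lengths = rng.integers(500, 5000, size=n_genes).astype(float)
    gene_index = pd.Index(genes, name="gene")
    return BulkSim(
        counts=pd.DataFrame(counts, index=gene_index, columns=groups.index),
        groups=groups,
        gene_lengths=pd.Series(lengths, index=gene_index, name="length"),
        true_log2_effect=pd.Series(effect, index=gene_index, name="log2_effect"),
    )


# ---------------------------------------------------------------------------
# methylome

_HLA_TSS_POS = {"HLA-A": 1_000_000, "HLA-B": 2_000_000, "HLA-C": 3_000_000}
_CONSENSUS_START = 10_000_000
_CONSENSUS_SPACING = 50_000
_CONSENSUS_WIDTH = 1_000
_N_CONSENSUS = 10


@dataclass(frozen=True)
class MethylomeSim:
    beta: pd.DataFrame            # probes x samples, values in [0, 1]
    groups: pd.Series             # sample -> group label
    annotation: pd.DataFrame      # probe, chrom, pos (1-based), masked
    planted_hyper: pd.Series = field(repr=False)
    planted_hypo: pd.Series = field(repr=False)
    peaks: dict[str, list[GenomicInterval]] = field(repr=False, default=None)
    tss: pd.DataFrame = field(repr=False, default=None)
    consensus_truth: list[GenomicInterval] = field(repr=False, default=None)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def simulate_methylome(config: SyntheticConfig) -> MethylomeSim:
    """Simulate an EPIC-like beta matrix plus the genomic side inputs.

    Layout (all on chr1):

    * three "HLA" promoters at fixed TSS positions; ``n_dms_probes``
      planted probes sit within +/-1.5 kb of them and gain
      ``dms_delta_beta`` in the ic-GSC group (promoter hypermethylation);
    * ten 1-kb consensus OSN binding intervals; the three per-factor
      peak files pad these differently so their triple intersection is
      exactly the planted intervals.  Probes inside them lose
      methylation in the ic-GSC group; additional unplanted probes tile
      the +/-10 kb flanks so metaprofiles have baseline bins;
    * the remaining probes are background, placed on chr2.

    Beta values are logit-normal around the planted group means with
    noise sd ``beta_noise_sd`` on the logit scale, clipped to
    [1e-6, 1-1e-6].
    """
    if config.n_probes < 1000:
        raise ValueError("n_probes must be >= 1000")
    _, _, rng = config._streams()
    samples = [f"{GROUP_DC}{i + 1}" for i in range(config.n_bulk_reps)] + [
        f"{GROUP_IC}{i + 1}" for i in range(config.n_bulk_reps)
    ]
    groups = pd.Series(
        [GROUP_DC] * config.n_bulk_reps + [GROUP_IC] * config.n_bulk_reps,
        index=pd.Index(samples, name="sample"),
        name="group",
    )

    # --- genomic scaffolding -------------------------------------------------
    tss_rows = [("chr1", pos, "+", g) for g, pos in _HLA_TSS_POS.items()]
    for i in range(20):  # bystander promoters, no planted signal
        tss_rows.append(("chr1", 5_000_000 + i * 100_000, "+", f"gene{i:05d}"))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "gene"])

    consensus = [
        GenomicInterval(
            "chr1",
            _CONSENSUS_START + i * _CONSENSUS_SPACING,
            _CONSENSUS_START + i * _CONSENSUS_SPACING + _CONSENSUS_WIDTH,
        )
        for i in range(_N_CONSENSUS)
    ]
    # pad each factor's peaks differently; the triple intersection is exact
    peaks = {
        "OCT4": [GenomicInterval(c.chrom, c.start - 200, c.end + 100) for c in consensus],
        "SOX2": [GenomicInterval(c.chrom, c.start - 100, c.end + 200) for c in consensus],
        "NANOG": [GenomicInterval(c.chrom, c.start, c.end) for c in consensus],
    }
    # factor-private peaks that must not survive the triple intersection
    peaks["OCT4"].append(GenomicInterval("chr1", 20_000_000, 20_001_000))
    peaks["SOX2"].append(GenomicInterval("chr1", 21_000_000, 21_001_000))
    peaks["NANOG"].append(GenomicInterval("chr1", 22_000_000, 22_001_000))

    # --- probe placement -----------------------------------------------------
    probe_chrom: list[str] = []
    probe_pos: list[int] = []
    hyper_flags: list[bool] = []
    hypo_flags: list[bool] = []

    hla_genes = list(_HLA_TSS_POS)
    for j in range(config.n_dms_probes):  # planted promoter probes
        gene = hla_genes[j % 3]
        offset = int(rng.integers(-1500, 1501))
        probe_chrom.append("chr1")
        probe_pos.append(_HLA_TSS_POS[gene] + offset)
        hyper_flags.append(True)
        hypo_flags.append(False)

    # unplanted probes at the bystander promoters (null on both axes)
    for pos in tss["pos"].iloc[3:]:
        for offset in (-1200, -400, 0, 400, 1200):
            probe_chrom.append("chr1")
            probe_pos.append(int(pos) + offset)
            hyper_flags.append(False)
            hypo_flags.append(False)

    for c in consensus:  # planted probes inside consensus intervals
        mid = (c.start + c.end) // 2
        for off in (-300, 0, 300):
            probe_chrom.append("chr1")
            probe_pos.append(mid + off + 1)  # 1-based
            hyper_flags.append(False)
            hypo_flags.append(True)
        for off in range(-9800, 10000, 1200):  # unplanted flank probes
            if abs(off) <= _CONSENSUS_WIDTH:
                continue
            probe_chrom.append("chr1")
            probe_pos.append(mid + off + 1)
            hyper_flags.append(False)
            hypo_flags.append(False)

    n_bg = config.n_probes - len(probe_pos)
    if n_bg < 0:
        raise ValueError("n_probes too small for the planted probe layout")
    bg_pos = np.sort(rng.choice(50_000_000, size=n_bg, replace=False)) + 1
    probe_chrom.extend(["chr2"] * n_bg)
    probe_pos.extend(int(p) for p in bg_pos)
    hyper_flags.extend([False] * n_bg)
    hypo_flags.extend([False] * n_bg)

    n_probes = len(probe_pos)
    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    annotation = pd.DataFrame(
        {
            "probe": probe_ids,
            "chrom": probe_chrom,
            "pos": probe_pos,
            "masked": False,
        }
    )
    hyper = np.array(hyper_flags)
    hypo = np.array(hypo_flags)

    # --- beta values ---------------------------------------------------------
    baseline = rng.beta(2.0, 8.0, size=n_probes)  # mean ~0.2, CpG-island-biased panel
    baseline = np.clip(baseline, 0.02, 0.95)
    mean_dc = baseline.copy()
    mean_ic = baseline.copy()
    mean_ic[hyper] = np.clip(baseline[hyper] + config.dms_delta_beta, None, 0.97)
    mean_ic[hypo] = np.clip(baseline[hypo] * 0.3, 0.02, None)

    n_reps = config.n_bulk_reps
    means = np.concatenate(
        [np.tile(mean_dc[:, None], (1, n_reps)), np.tile(mean_ic[:, None], (1, n_reps))],
        axis=1,
    )
    noise = rng.normal(0.0, config.beta_noise_sd, size=means.shape)
    beta = 1.0 / (1.0 + np.exp(-(_logit(means) + noise)))
    beta = np.clip(beta, 1e-6, 1.0 - 1e-6)

    probe_index = pd.Index(probe_ids, name="probe")
    return MethylomeSim(
        beta=pd.DataFrame(beta, index=probe_index, columns=groups.index),
        groups=groups,
        annotation=annotation,
        planted_hyper=pd.Series(hyper, index=probe_index, name="planted_hyper"),
        planted_hypo=pd.Series(hypo, index=probe_index, name="planted_hypo"),
        peaks=peaks,
        tss=tss,
        consensus_truth=consensus,
    )
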