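"""Single-cell identification of core glioma stem cells (c-GSCs).

A c-GSC is defined as a tumor cell concurrently in the upper expression
quartile of the three embryonic-stem-cell core transcription factors
OCT4 (POU5F1), SOX2 and NANOG ("OSN").  This module implements the
marker-combination classifier, per-patient cohort summaries, the HLA
class I expression gradient across the eight OSN categories, and
Wilcoxon rank-sum differential expression between c-GSCs and the tumor
bulk with Benjamini-Hochberg FDR control.

Expression matrices are plain pandas DataFrames with genes as rows and
cells as columns; per-cell patient labels travel as a Series indexed by
cell id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MARKERS = ("OCT4", "SOX2", "NANOG")
DEFAULT_HLA_GENES = ("HLA-A", "HLA-B", "HLA-C")

#: canonical ordering of the eight marker combinations, from triple-negative
#: (OSN-) to triple-positive (OSN+), used for gradient profiles.
OSN_CATEGORIES = (
    "O-S-N-",
    "O+S-N-",
    "O-S+N-",
    "O-S-N+",
    "O+S+N-",
    "O+S-N+",
    "O-S+N+",
    "O+S+N+",
)
TRIPLE_POSITIVE = "O+S+N+"


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate cell id: {dup!r}")


def filter_genes(matrix: pd.DataFrame, max_zero_frac: float = 0.95) -> pd.DataFrame:
    """Drop genes with no expression in more than ``max_zero_frac`` of cells.

    A gene is retained iff its fraction of zero-valued cells is at most
    ``max_zero_frac`` (equivalently, it is expressed in at least
    ``1 - max_zero_frac`` of cells).  The cell set is unchanged.
    """
    if not 0 < max_zero_frac < 1:
        raise ValueError(f"max_zero_frac must be in (0, 1), got {max_zero_frac}")
    _check_matrix(matrix)
    zero_frac = (matrix.to_numpy() == 0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    if not keep.any():
        raise ValueError(
            f"all {matrix.shape[0]} genes removed at zero-fraction "
            f"threshold {max_zero_frac}"
        )
    return matrix.loc[keep]


@dataclass(frozen=True)
class QuartileThresholds:
    """Upper-quartile (Q3) expression thresholds for the three OSN markers."""

    q3: dict[str, float]

    def __getitem__(self, marker: str) -> float:
        return self.q3[marker]


def marker_thresholds(
    matrix: pd.DataFrame, markers: tuple[str, str, str] = DEFAULT_MARKERS
) -> QuartileThresholds:
    """Per-marker 75th percentile over all cells (linear-interpolation quantile)."""
    missing = [m for m in markers if m not in matrix.index]
    if missing:
        raise KeyError(f"marker gene(s) not in matrix: {', '.join(missing)}")
    q3 = {
        m: float(np.quantile(matrix.loc[m].to_numpy(dtype=float), 0.75))
        for m in markers
    }
    return QuartileThresholds(q3=q3)


def classify_osn(
    matrix: pd.DataFrame,
    thresholds: QuartileThresholds,
    markers: tuple[str, str, str] = DEFAULT_MARKERS,
) -> pd.DataFrame:
    """Assign each cell one of the eight OSN categories.

    A marker is "high" iff its expression is strictly greater than the
    marker's Q3; ties at the threshold are low.  ``is_cgsc`` is true iff
    all three markers are high.

    Returns a DataFrame indexed by cell with boolean columns per marker,
    the 8-way ``category`` string and ``is_cgsc``.
    """
    letters = ("O", "S", "N")
    high = {}
    for letter, m in zip(letters, markers):
        high[letter] = matrix.loc[m].to_numpy(dtype=float) > thresholds[m]
    category = np.array(
        [
            f"O{'+' if o else '-'}S{'+' if s else '-'}N{'+' if n else '-'}"
            for o, s, n in zip(high["O"], high["S"], high["N"])
        ]
    )
    out = pd.DataFrame(
        {
            "O_high": high["O"],
            "S_high": high["S"],
            "N_high": high["N"],
            "category": category,
            "is_cgsc": high["O"] & high["S"] & high["N"],
        },
        index=matrix.columns.copy(),
    )
    out.index.name = "cell"
    return out


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level c-GSC content, pooled and per patient."""

    pooled_fraction_pct: float
    per_patient_pct: pd.Series = field(repr=False)
    mean_pct: float
    sem_pct: float
    sd_pct: float
    n_patients: int
    n_patients_with_cgsc: int

    @property
    def pct_patients_with_cgsc(self) -> float:
        return 100.0 * self.n_patients_with_cgsc / self.n_patients


def cohort_summary(labels: pd.DataFrame, patient_of: pd.Series) -> CohortSummary:
    """Summarize c-GSC prevalence pooled over all cells and per patient.

    ``pooled_fraction_pct`` is 100 x (#c-GSC)/(#cells) over the pooled
    cohort; per-patient fractions are computed over each patient's own
    cells (patients with zero cells are excluded).  The across-patient
    mean is reported with both SEM and SD.
    """
    flags = labels["is_cgsc"].astype(bool)
    patients = patient_of.reindex(flags.index)
    if patients.isna().any():
        missing = flags.index[patients.isna()][0]
        raise ValueError(f"cell {missing!r} has no patient label")
    pooled = 100.0 * flags.mean()
    per_patient = 100.0 * flags.groupby(patients, observed=True).mean()
    per_patient.index.name = "patient"
    n_pat = len(per_patient)
    mean = float(per_patient.mean())
    if n_pat < 2:
        warnings.warn("SEM undefined with a single patient; reporting 0")
        sem = sd = 0.0
    else:
        sd = float(per_patient.std(ddof=1))
        sem = sd / np.sqrt(n_pat)
    with_cgsc = int(
        flags.groupby(patients, observed=True).any().sum()
    )
    return CohortSummary(
        pooled_fraction_pct=float(pooled),
        per_patient_pct=per_patient,
        mean_pct=mean,
        sem_pct=float(sem),
        sd_pct=float(sd),
        n_patients=n_pat,
        n_patients_with_cgsc=with_cgsc,
    )


@dataclass(frozen=True)
class GradientProfile:
    """Mean HLA expression per OSN category, raw and rescaled to OSN+."""

    means: pd.DataFrame      # categories x genes; NaN for empty categories
    rescaled: pd.DataFrame   # means / means.loc["O+S+N+"]


def hla_gradient(
    matrix: pd.DataFrame,
    labels: pd.DataFrame,
    hla_genes: tuple[str, ...] = DEFAULT_HLA_GENES,
) -> GradientProfile:
    """HLA class I expression gradient across the eight OSN categories.

    For each category and each HLA gene, the mean expression over the
    category's cells; categories with no cells are reported as missing
    (NaN), never as zero.  The rescaled track divides each gene's track
    by its OSN+ (triple-positive) mean, so the OSN+ entry is 1 whenever
    that mean is positive.
    """
    missing = [g for g in hla_genes if g not in matrix.index]
    if missing:
        raise KeyError(f"HLA gene(s) not in matrix: {', '.join(missing)}")
    cats = labels["category"].reindex(matrix.columns)
    sub = matrix.loc[list(hla_genes)]
    means = pd.DataFrame(
        np.nan, index=list(OSN_CATEGORIES), columns=list(hla_genes), dtype=float
    )
    for cat, cells in sub.columns.groupby(cats).items():
        means.loc[cat] = sub[cells].mean(axis=1)
    means.index.name = "category"
    ref = means.loc[TRIPLE_POSITIVE]
    with np.errstate(divide="ignore", invalid="ignore"):
        rescaled = means.divide(ref.where(ref > 0), axis=1)
    return GradientProfile(means=means, rescaled=rescaled)


def wilcoxon_deg(
    matrix: pd.DataFrame,
    is_cgsc: pd.Series | np.ndarray,
    q_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential expression between c-GSCs and the tumor bulk.

    Per gene: a two-sided Wilcoxon rank-sum test (normal approximation
    with tie correction) of c-GSC cells vs all remaining cells, BH-FDR
    across genes, and a pseudocounted log2 fold change
    ``log2((mean_cgsc + eps) / (mean_bulk + eps))``.  A gene is a DEG iff
    q < ``q_threshold`` and |log2FC| > ``lfc_threshold``.
    """
    if isinstance(is_cgsc, pd.Series):
        is_cgsc = is_cgsc.reindex(matrix.columns).to_numpy()
    is_cgsc = np.asarray(is_cgsc, dtype=bool)
    n1, n0 = int(is_cgsc.sum()), int((~is_cgsc).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(
            f"both groups need >= 2 cells (c-GSC: {n1}, bulk: {n0})"
        )
    values = matrix.to_numpy(dtype=float)
    x = values[:, is_cgsc]
    y = values[:, ~is_cgsc]
    res = stats.mannwhitneyu(x, y, axis=-1, method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant across all cells carry no rank information
    constant = values.max(axis=1) == values.min(axis=1)
    p[constant] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    mean_x = x.mean(axis=1)
    mean_y = y.mean(axis=1)
    effect = np.log2((mean_x + pseudocount) / (mean_y + pseudocount))
    effect[constant] = 0.0
    is_deg = (q < q_threshold) & (np.abs(effect) > lfc_threshold)
    table = pd.DataFrame(
        {
            "mean_cgsc": mean_x,
            "mean_bulk": mean_y,
            "log2fc": effect,
            "p": p,
            "q": q,
            "direction": np.where(effect > 0, "up", "down"),
            "is_deg": is_deg,
        },
        index=matrix.index.copy(),
    )
    table.index.name = "gene"
    return table
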