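"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices travel as TSV with genes (or probes) as rows, or as
MatrixMarket MTX with features/barcodes sidecars for sparse single-cell
counts.  Peaks are 3+ column BED (0-based, half-open); TSS tables and
cell metadata are TSV.  GMT follows the usual tab-separated layout:
set name, description, then member genes.  Lines starting with '#' are
treated as comments everywhere.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .intervals import GenomicInterval


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Dense matrix with row ids in the first column (genes/probes) and
    one column per cell/sample."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row id {dup!r}")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        matrix.to_csv(fh, sep="\t")


def read_mtx(matrix_path: str | Path, features_path: str | Path,
             barcodes_path: str | Path) -> pd.DataFrame:
    """Sparse MatrixMarket counts with feature/barcode sidecar TSVs
    (first column = id), returned as a dense genes x cells DataFrame."""
    m = spio.mmread(matrix_path)
    genes = pd.read_csv(features_path, sep="\t", header=None)[0]
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0]
    m = np.asarray(m.todense()) if sparse.issparse(m) else np.asarray(m)
    if m.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {m.shape} does not match {len(genes)} features "
            f"x {len(cells)} barcodes"
        )
    return pd.DataFrame(m, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(cells, name="cell"))


def write_mtx(matrix: pd.DataFrame, matrix_path: str | Path,
              features_path: str | Path, barcodes_path: str | Path) -> None:
    spio.mmwrite(str(matrix_path), sparse.csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.index).to_csv(features_path, sep="\t", header=False, index=False)
    pd.Series(matrix.columns).to_csv(barcodes_path, sep="\t", header=False, index=False)


def read_cell_meta(path: str | Path) -> pd.Series:
    """Cell metadata TSV with a first id column and a required
    'patient' column; returns the cell -> patient mapping."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "patient" not in df.columns:
        raise ValueError(f"{path}: missing required column 'patient'")
    return df["patient"]


def read_design(path: str | Path) -> pd.Series:
    """Bulk design TSV with columns (sample, group)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: need columns 'sample' and 'group'")
    return df.set_index("sample")["group"]


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "length"} <= set(df.columns):
        raise ValueError(f"{path}: need columns 'gene' and 'length'")
    return df.set_index("gene")["length"].astype(float)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """3+ column BED (0-based, half-open); malformed lines are reported
    with their line number."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[3] if len(fields) > 3 else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"\t{iv.name}" if iv.name else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


def read_tss(path: str | Path) -> pd.DataFrame:
    """TSS TSV with columns (chrom, pos, strand, gene); pos is 1-based."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"chrom", "pos", "strand", "gene"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    return df


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Probe annotation TSV with columns (probe, chrom, pos[, masked])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"probe", "chrom", "pos"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    if "masked" not in df.columns:
        df["masked"] = False
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collection: one set per line, tab-separated
    (name, description, gene, gene, ...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected name, description and >= 1 gene"
                )
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
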