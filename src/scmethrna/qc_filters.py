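"""Cell-level quality-control gates for both omics layers.

RNA cells are kept when they clear a conjunction of read-depth, detected-
gene, total-count and mitochondrial-percentage rules (lower bounds
inclusive, upper bounds inclusive).  Bisulfite cells are kept when enough
CpGs are covered and the global CpG methylation percentage lies strictly
inside the (30, 70) window - hypo- or hyper-converted libraries fall
outside it.  All thresholds are configurable; the defaults are the
full-genome study values and are meant to be scaled down for synthetic
genomes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneRecord
from .methylome_regions import _as_frame


@dataclass(frozen=True)
class RnaQcThresholds:
    min_reads: float = 25_000
    min_genes: float = 5_000
    max_genes: float = 7_500
    max_counts: float = 2_000_000
    max_pct_mito: float = 5.0


@dataclass(frozen=True)
class BsQcThresholds:
    min_cpgs: int = 500_000
    min_global_meth_pct: float = 30.0  # strict lower bound
    max_global_meth_pct: float = 70.0  # strict upper bound


def rna_cell_qc(
    matrix: CountMatrix,
    gene_table: Sequence[GeneRecord],
    read_counts: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-cell RNA QC metrics.

    ``n_reads`` comes from ``read_counts`` metadata when given, else the
    column sum stands in for it.  ``pct_mito`` is 100 x mitochondrial
    counts / total counts, defined as 0 (with a warning) for an all-zero
    cell.
    """
    gene_idx = {g.gene_id: g for g in gene_table}
    is_mito = np.array([gene_idx[g].is_mito if g in gene_idx else False
                        for g in matrix.gene_ids])
    counts = matrix.counts
    n_counts = counts.sum(axis=0)
    n_genes = (counts > 0).sum(axis=0)
    mito_counts = counts[is_mito].sum(axis=0) if is_mito.any() else np.zeros(len(matrix.cell_ids))
    if read_counts is not None:
        missing = set(matrix.cell_ids) - set(read_counts)
        if missing:
            raise ValueError(f"read_counts missing cells: {sorted(missing)}")
        n_reads = np.array([read_counts[c] for c in matrix.cell_ids], dtype=float)
    else:
        n_reads = n_counts.astype(float)
    if np.any(n_counts == 0):
        warnings.warn(
            f"{int(np.sum(n_counts == 0))} all-zero cell(s); pct_mito set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_counts > 0, 100.0 * mito_counts / n_counts, 0.0)
    return pd.DataFrame(
        {
            "cell_id": matrix.cell_ids,
            "n_reads": n_reads,
            "n_genes_detected": n_genes.astype(int),
            "n_counts": n_counts.astype(int),
            "pct_mito": pct_mito,
        }
    )


def filter_rna_cells(
    qc: pd.DataFrame, thresholds: RnaQcThresholds = RnaQcThresholds()
) -> tuple[list[str], pd.DataFrame]:
    """Conjunctive RNA gates; every excluded cell lists each violated rule."""
    t = thresholds
    checks = {
        f"n_reads<{t.min_reads:g}": qc["n_reads"] >= t.min_reads,
        f"n_genes<{t.min_genes:g}": qc["n_genes_detected"] >= t.min_genes,
        f"n_genes>{t.max_genes:g}": qc["n_genes_detected"] <= t.max_genes,
        f"n_counts>{t.max_counts:g}": qc["n_counts"] <= t.max_counts,
        f"pct_mito>{t.max_pct_mito:g}": qc["pct_mito"] <= t.max_pct_mito,
    }
    passed = np.logical_and.reduce(list(checks.values()))
    reasons = [
        ";".join(rule for rule, ok in checks.items() if not ok.iloc[i])
        for i in range(len(qc))
    ]
    report = qc.copy()
    report["pass"] = passed
    report["reasons"] = reasons
    kept = report.loc[report["pass"], "cell_id"].tolist()
    return kept, report


def bs_cell_qc(cells: Mapping[str, object]) -> pd.DataFrame:
    """Per-cell bisulfite QC: CpGs covered and global methylation percent."""
    rows = []
    for cell_id, cell in cells.items():
        df = _as_frame(cell)
        n_meth = int(df["n_meth"].sum()) if len(df) else 0
        n_tot = n_meth + (int(df["n_unmeth"].sum()) if len(df) else 0)
        rows.append(
            {
                "cell_id": cell_id,
                "n_cpgs_covered": int(len(df)),
                "global_meth_pct": 100.0 * n_meth / n_tot if n_tot else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "n_cpgs_covered", "global_meth_pct"])


def filter_bs_cells(
    qc: pd.DataFrame, thresholds: BsQcThresholds = BsQcThresholds()
) -> tuple[list[str], pd.DataFrame]:
    """Keep cells with >= min CpGs and methylation strictly inside (30, 70)%."""
    t = thresholds
    checks = {
        f"n_cpgs<{t.min_cpgs:g}": qc["n_cpgs_covered"] >= t.min_cpgs,
        f"meth<={t.min_global_meth_pct:g}%": qc["global_meth_pct"] > t.min_global_meth_pct,
        f"meth>={t.max_global_meth_pct:g}%": qc["global_meth_pct"] < t.max_global_meth_pct,
    }
    passed = np.logical_and.reduce(list(checks.values()))
    reasons = [
        ";".join(rule for rule, ok in checks.items() if not ok.iloc[i])
        for i in range(len(qc))
    ]
    report = qc.copy()
    report["pass"] = passed
    report["reasons"] = reasons
    kept = report.loc[report["pass"], "cell_id"].tolist()
    return kept, report


def tss_methylation_flags(
    cells: Mapping[str, object],
    gene_table: Sequence[GeneRecord],
    flank: int = 1000,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Optional diagnostic: flag cells with outlying mean TSS-area methylation.

    Computes each cell's mean methylation over TSS +- ``flank`` bp, then the
    z-score across cells; |z| > ``z_threshold`` flags a cell.  Reported only
    - this diagnostic never excludes cells.
    """
    from .methylome_regions import GenomicRegion, aggregate_region

    regions = []
    for g in gene_table:
        tss0 = g.tss - 1
        start = max(0, tss0 - flank)
        regions.append(
            GenomicRegion(g.chrom, start, tss0 + flank, "promoter",
                          f"tssflank:{g.gene_id}", gene_id=g.gene_id)
        )
    mat = aggregate_region(cells, regions, min_cov_per_cpg=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_cell = np.nanmean(mat.meth_fraction, axis=0)
    mean, sd = np.nanmean(per_cell), np.nanstd(per_cell, ddof=1)
    z = (per_cell - mean) / sd if sd > 0 else np.zeros_like(per_cell)
    return pd.DataFrame(
        {
            "cell_id": mat.cell_ids,
            "tss_meth_mean": per_cell,
            "tss_meth_z": z,
            "flagged": np.abs(z) > z_threshold,
        }
    )
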