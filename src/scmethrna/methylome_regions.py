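"""Region-level methylation quantification.

Aggregates sparse per-cell CpG calls into region x cell methylation
matrices over annotated feature classes (CpG islands, promoters, gene
bodies, transposons, imprinted gDMRs), tiles the genome into fixed-width
windows, and detects variably methylated regions (VMRs) as merged runs of
high cell-to-cell-variance windows.

Pooling within a region is read-weighted by default (sum methylated reads
over qualifying CpGs, divide by total reads): at 0.5-3x single-cell
coverage, per-CpG fractions are too unstable to average.  A
``pooling="cpg_mean"`` alternative (mean of per-CpG fractions) is provided.
Only CpGs with coverage >= ``min_cov_per_cpg`` (default 5 reads) enter a
region's estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CpGCall, GenomicRegion, calls_to_frame


@dataclass
class RegionMethylationMatrix:
    """regions x cells methylation fractions with coverage metadata.

    ``meth_fraction`` is NaN exactly where ``n_cpgs_covered`` is zero.
    """

    regions: list[GenomicRegion]
    cell_ids: list[str]
    meth_fraction: np.ndarray  # float, NaN = missing
    n_cpgs_covered: np.ndarray  # int
    total_reads: np.ndarray  # int

    def __post_init__(self) -> None:
        shape = (len(self.regions), len(self.cell_ids))
        for name in ("meth_fraction", "n_cpgs_covered", "total_reads"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")
        missing = self.n_cpgs_covered == 0
        if not np.array_equal(missing, np.isnan(self.meth_fraction)):
            raise ValueError("meth_fraction must be NaN exactly where n_cpgs_covered == 0")

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.meth_fraction, index=self.region_ids, columns=self.cell_ids)

    def subset_regions(self, index: Sequence[int]) -> "RegionMethylationMatrix":
        idx = np.asarray(index)
        return RegionMethylationMatrix(
            [self.regions[i] for i in idx],
            self.cell_ids,
            self.meth_fraction[idx],
            self.n_cpgs_covered[idx],
            self.total_reads[idx],
        )


@dataclass(frozen=True)
class VmrCall:
    """A merged run of high-variance windows."""

    region: GenomicRegion
    variance_across_cells: float
    rank: int
    n_windows: int = 1


def _as_frame(cell) -> pd.DataFrame:
    if isinstance(cell, pd.DataFrame):
        return cell
    return calls_to_frame(cell)


def aggregate_region(
    cells: Mapping[str, object],
    regions: Sequence[GenomicRegion],
    min_cov_per_cpg: int = 5,
    pooling: str = "reads",
) -> RegionMethylationMatrix:
    """Aggregate per-cell CpG calls over regions.

    ``cells`` maps cell id to either a list of :class:`CpGCall` or the
    canonical methylome frame.  A CpG belongs to a region iff its 0-based
    cytosine position lies in ``[start, end)``; overlapping regions are
    allowed and a CpG may serve several feature classes.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if pooling not in ("reads", "cpg_mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    cell_ids = list(cells.keys())
    n_r, n_c = len(regions), len(cell_ids)
    meth = np.zeros((n_r, n_c))
    ncpg = np.zeros((n_r, n_c), dtype=np.int64)
    reads = np.zeros((n_r, n_c), dtype=np.int64)

    # per-region arrays grouped by chromosome, for vectorized searchsorted
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in regions}:
        idx = np.array([i for i, r in enumerate(regions) if r.chrom == chrom])
        starts = np.array([regions[i].start for i in idx])
        ends = np.array([regions[i].end for i in idx])
        by_chrom[chrom] = (idx, starts, ends)

    for j, cid in enumerate(cell_ids):
        df = _as_frame(cells[cid])
        if len(df) == 0:
            continue
        cov = df["n_meth"].to_numpy() + df["n_unmeth"].to_numpy()
        keep = cov >= min_cov_per_cpg
        if not keep.any():
            continue
        sub = df.loc[keep]
        pos0 = sub["pos"].to_numpy(np.int64) - 1  # internal 0-based
        nm = sub["n_meth"].to_numpy(np.int64)
        nt = nm + sub["n_unmeth"].to_numpy(np.int64)
        frac = nm / nt
        chroms = sub["chrom"].to_numpy(str)
        order = np.lexsort((pos0, chroms))
        pos0, nm, nt, frac, chroms = (
            pos0[order], nm[order], nt[order], frac[order], chroms[order]
        )
        for chrom, (idx, starts, ends) in by_chrom.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            p = pos0[sel]
            cm = np.concatenate(([0], np.cumsum(nm[sel])))
            ct = np.concatenate(([0], np.cumsum(nt[sel])))
            cf = np.concatenate(([0.0], np.cumsum(frac[sel])))
            lo = np.searchsorted(p, starts, side="left")
            hi = np.searchsorted(p, ends, side="left")
            n = hi - lo
            ncpg[idx, j] = n
            reads[idx, j] = ct[hi] - ct[lo]
            with np.errstate(invalid="ignore", divide="ignore"):
                if pooling == "reads":
                    meth[idx, j] = np.where(n > 0, (cm[hi] - cm[lo]) / (ct[hi] - ct[lo]), np.nan)
                else:
                    meth[idx, j] = np.where(n > 0, (cf[hi] - cf[lo]) / n, np.nan)
    meth[ncpg == 0] = np.nan
    return RegionMethylationMatrix(list(regions), cell_ids, meth, ncpg, reads)


def tile_windows(
    genome: Mapping[str, int], width: int = 1000
) -> list[GenomicRegion]:
    """Tile each chromosome into adjacent non-overlapping windows.

    ``genome`` maps chromosome name to length in bp; the last window of a
    chromosome may be shorter than ``width``.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    regions: list[GenomicRegion] = []
    for chrom, length in genome.items():
        for start in range(0, length, width):
            end = min(start + width, length)
            regions.append(
                GenomicRegion(
                    chrom, start, end, "window1kb", f"window1kb:{chrom}:{start}-{end}"
                )
            )
    return regions


def detect_vmrs(
    window_matrix: RegionMethylationMatrix,
    top_fraction: float = 0.02,
    min_cells: int | None = None,
) -> list[VmrCall]:
    """Rank genome windows by cell-to-cell methylation variance and merge.

    Windows covered in fewer than ``min_cells`` cells (default: half of all
    cells, rounded up) are ineligible.  The top ``top_fraction`` of eligible
    windows by sample variance are selected and runs of genomically adjacent
    selected windows are merged into single variable-length VMRs, ranked by
    the merged region's maximum window variance.
    """
    n_cells = len(window_matrix.cell_ids)
    if min_cells is None:
        min_cells = math.ceil(n_cells / 2)
    frac = window_matrix.meth_fraction
    n_obs = np.sum(~np.isnan(frac), axis=1)
    eligible = np.flatnonzero((n_obs >= min_cells) & (n_obs >= 2))
    if eligible.size == 0:
        warnings.warn("no eligible windows for VMR detection", stacklevel=2)
        return []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(frac[eligible], axis=1, ddof=1)
    n_select = max(1, int(math.floor(top_fraction * eligible.size)))
    # stable: rank by variance desc, tie-break by genomic order
    order = np.lexsort((eligible, -var))
    selected = set(eligible[order[:n_select]].tolist())
    var_of = dict(zip(eligible.tolist(), var.tolist()))

    # merge genomically adjacent selected windows
    sel_sorted = sorted(
        selected,
        key=lambda i: (window_matrix.regions[i].chrom, window_matrix.regions[i].start),
    )
    merged: list[tuple[str, int, int, float, int]] = []
    for i in sel_sorted:
        r = window_matrix.regions[i]
        v = var_of[i]
        if merged and merged[-1][0] == r.chrom and merged[-1][2] == r.start:
            chrom, start, _, vmax, n = merged[-1]
            merged[-1] = (chrom, start, r.end, max(vmax, v), n + 1)
        else:
            merged.append((r.chrom, r.start, r.end, v, 1))
    merged.sort(key=lambda t: (-t[3], t[0], t[1]))
    calls = []
    for rank, (chrom, start, end, vmax, n) in enumerate(merged, start=1):
        region = GenomicRegion(chrom, start, end, "VMR", f"VMR:{chrom}:{start}-{end}")
        calls.append(VmrCall(region, vmax, rank, n))
    return calls


def promoter_regions(
    genes, flank: int = 2000, chrom_sizes: Mapping[str, int] | None = None
) -> list[GenomicRegion]:
    """Promoters as a symmetric window of ``flank`` bp around the TSS.

    The window is centered on the TSS regardless of strand (internal
    0-based TSS t gives [t - flank, t + flank)), clipped to the chromosome.
    """
    out = []
    for g in genes:
        tss0 = g.tss - 1
        start = max(0, tss0 - flank)
        end = tss0 + flank
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g.chrom])
        out.append(
            GenomicRegion(
                g.chrom, start, end, "promoter", f"promoter:{g.gene_id}",
                gene_id=g.gene_id, strand=g.strand,
            )
        )
    return out


def gene_body_regions(genes) -> list[GenomicRegion]:
    """Gene bodies (coding regions) as 0-based half-open intervals."""
    return [
        GenomicRegion(
            g.chrom, g.gene_start - 1, g.gene_end, "gene_body",
            f"gene_body:{g.gene_id}", gene_id=g.gene_id, strand=g.strand,
        )
        for g in genes
    ]


def imprint_report(
    matrix: RegionMethylationMatrix,
    group_labels: Mapping[str, str],
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Per imprinted-gDMR group means and an 'appropriate' stability flag.

    Germline DMRs of imprinted genes are expected to keep their methylation
    irrespective of the maturation condition; a region is flagged
    appropriate iff the absolute group difference is <= ``tolerance``.
    This is a descriptive report, not a statistical test.
    """
    labels = [group_labels[c] for c in matrix.cell_ids]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {uniq}")
    mask1 = np.array([l == uniq[0] for l in labels])
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, region in enumerate(matrix.regions):
            m1 = np.nanmean(matrix.meth_fraction[i, mask1])
            m2 = np.nanmean(matrix.meth_fraction[i, ~mask1])
            diff = m1 - m2
            rows.append(
                {
                    "region_id": region.region_id,
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    f"mean_{uniq[0]}": m1,
                    f"mean_{uniq[1]}": m2,
                    "difference": diff,
                    "appropriate": bool(abs(diff) <= tolerance) if np.isfinite(diff) else False,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "chrom", "start", "end",
            f"mean_{uniq[0]}", f"mean_{uniq[1]}", "difference", "appropriate",
        ],
    )
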