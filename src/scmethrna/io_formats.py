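"""Readers and writers for the pipeline's on-disk artifacts.

All text inputs may be gzip-compressed (detected by the ``.gz`` suffix or
the gzip magic bytes).  The internal coordinate convention is 0-based
half-open for every interval; Bismark coverage files use 1-based inclusive
positions and are converted only at this boundary.  ``CpGCall.pos`` keeps
the 1-based cytosine position exactly as printed in the coverage file; when
a call is assigned to an interval the comparison is ``pos - 1 in
[start, end)``.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = frozenset(
    {"CGI", "promoter", "gene_body", "transposon", "window1kb", "VMR", "imprinted_gDMR"}
)

#: columns of the canonical per-cell methylome frame
CPG_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]


class CpGCall(NamedTuple):
    """One CpG site's read counts in one cell.

    ``pos`` is the 1-based position of the CpG cytosine (Bismark
    convention).  Stored calls always have ``n_meth + n_unmeth >= 1``.
    """

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def fraction(self) -> float:
        return self.n_meth / self.coverage


@dataclass(frozen=True)
class GenomicRegion:
    """An annotated genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    feature_class: str
    region_id: str
    gene_id: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """One gene: 1-based inclusive body coordinates plus the TSS.

    For a ``+`` strand gene the TSS is ``gene_start``, for ``-`` it is
    ``gene_end``; either way ``gene_start <= tss <= gene_end``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_start: int
    gene_end: int
    is_mito: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (self.gene_start <= self.tss <= self.gene_end):
            raise ValueError(
                f"TSS {self.tss} outside gene body "
                f"[{self.gene_start}, {self.gene_end}] for {self.gene_id}"
            )


@dataclass
class CountMatrix:
    """genes x cells non-negative integer counts with ordered ids."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicated gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicated cell ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# generic text helpers


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        # mtime=0 keeps gzip output byte-reproducible across reruns
        raw = open(path, "wb")
        gz = gzip.GzipFile(fileobj=raw, mode="wb", mtime=0)
        return io.TextIOWrapper(gz, encoding="utf-8", newline="\n")
    return open(path, mode, newline="\n")


# ---------------------------------------------------------------------------
# Bismark coverage dialect


def read_bismark_cov(path: str | Path) -> list[CpGCall]:
    """Read a Bismark coverage file into per-site calls.

    Columns: chrom, start (1-based), end, percent methylation, count
    methylated, count unmethylated.  The percent column is never trusted:
    counts are authoritative and the fraction is recomputed.  Zero-coverage
    lines are dropped.
    """
    calls: list[CpGCall] = []
    n_percent_off = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                chrom = parts[0]
                pos = int(parts[1])
                percent = float(parts[3])
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed fields: {exc}") from exc
            cov = n_meth + n_unmeth
            if cov == 0:
                continue
            if abs(percent - 100.0 * n_meth / cov) > 0.5:
                n_percent_off += 1
            calls.append(CpGCall(chrom, pos, n_meth, n_unmeth))
    if n_percent_off:
        warnings.warn(
            f"{path}: {n_percent_off} line(s) with percent column inconsistent "
            "with counts (>0.5); counts used",
            stacklevel=2,
        )
    return calls


def write_bismark_cov(calls: Iterable[CpGCall] | pd.DataFrame, path: str | Path) -> None:
    """Write calls in the 6-column Bismark coverage dialect (percent recomputed)."""
    if isinstance(calls, pd.DataFrame):
        calls = frame_to_calls(calls)
    with _open_text(path, "wt") as fh:
        for c in calls:
            pct = 100.0 * c.n_meth / (c.n_meth + c.n_unmeth)
            fh.write(f"{c.chrom}\t{c.pos}\t{c.pos}\t{pct:g}\t{c.n_meth}\t{c.n_unmeth}\n")


def calls_to_frame(calls: Sequence[CpGCall]) -> pd.DataFrame:
    """Canonical per-cell methylome frame (chrom, pos, n_meth, n_unmeth)."""
    if len(calls) == 0:
        return pd.DataFrame({c: [] for c in CPG_COLUMNS}).astype(
            {"chrom": str, "pos": np.int64, "n_meth": np.int64, "n_unmeth": np.int64}
        )
    return pd.DataFrame(calls, columns=CPG_COLUMNS)


def frame_to_calls(frame: pd.DataFrame) -> list[CpGCall]:
    return [
        CpGCall(str(r.chrom), int(r.pos), int(r.n_meth), int(r.n_unmeth))
        for r in frame.itertuples(index=False)
    ]


def merge_symmetric_cpg(
    calls: Sequence[CpGCall], mode: str = "merge_adjacent"
) -> list[CpGCall]:
    """Collapse the two strands of a CpG dyad.

    In ``merge_adjacent`` mode, calls at positions p and p+1 on the same
    chromosome are summed into one call at p (the palindromic CpG seen from
    both strands); counts are conserved exactly.  ``keep_as_is`` is the
    identity.  Input must be sorted by (chrom, pos).
    """
    if mode not in ("merge_adjacent", "keep_as_is"):
        raise ValueError(f"unknown mode {mode!r}")
    calls = list(calls)
    for a, b in zip(calls, calls[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError("calls must be sorted by (chrom, pos)")
    if mode == "keep_as_is":
        return calls
    merged: list[CpGCall] = []
    i = 0
    while i < len(calls):
        c = calls[i]
        if (
            i + 1 < len(calls)
            and calls[i + 1].chrom == c.chrom
            and calls[i + 1].pos == c.pos + 1
        ):
            nxt = calls[i + 1]
            merged.append(
                CpGCall(c.chrom, c.pos, c.n_meth + nxt.n_meth, c.n_unmeth + nxt.n_unmeth)
            )
            i += 2
        else:
            merged.append(c)
            i += 1
    return merged


# ---------------------------------------------------------------------------
# BED feature files


def read_bed(path: str | Path, feature_class: str) -> list[GenomicRegion]:
    """Read a BED3/BED4 file (0-based half-open) tagged with a feature class.

    The region id is column 4 when present, else ``class:chrom:start-end``.
    """
    if feature_class not in FEATURE_CLASSES:
        raise ValueError(f"unknown feature class {feature_class!r}")
    regions: list[GenomicRegion] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: empty/inverted interval {start}-{end}"
                )
            region_id = (
                parts[3] if len(parts) >= 4 and parts[3] else f"{feature_class}:{chrom}:{start}-{end}"
            )
            regions.append(GenomicRegion(chrom, start, end, feature_class, region_id))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


# ---------------------------------------------------------------------------
# gene annotation table


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "gene_start", "gene_end", "is_mito"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the TSV gene table (gene_id, chrom, strand, tss, start, end, is_mito)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated gene ids")
    return [
        GeneRecord(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tss=int(r.tss),
            gene_start=int(r.gene_start),
            gene_end=int(r.gene_end),
            is_mito=bool(r.is_mito),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.strand, g.tss, g.gene_start, g.gene_end, int(g.is_mito))
            for g in genes
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(
    path: str | Path,
    rows_path: str | Path | None = None,
    cols_path: str | Path | None = None,
) -> CountMatrix:
    """Read a genes x cells count matrix.

    Either a TSV with a header row of cell ids and gene ids in the first
    column, or a MatrixMarket triplet (``path`` = .mtx plus row/column name
    files, one id per line).
    """
    path = Path(path)
    if rows_path is not None or cols_path is not None:
        if rows_path is None or cols_path is None:
            raise ValueError("MTX input needs both rows_path and cols_path")
        from scipy.io import mmread

        mat = mmread(str(path))
        counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        gene_ids = [ln.strip() for ln in _open_text(rows_path) if ln.strip()]
        cell_ids = [ln.strip() for ln in _open_text(cols_path) if ln.strip()]
        return CountMatrix(gene_ids, cell_ids, counts)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated gene ids")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated cell ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.round(values)):
        raise ValueError(f"{path}: non-integer counts")
    return CountMatrix([str(g) for g in df.index], [str(c) for c in df.columns], values)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# result tables


def write_results_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with a header, no index column."""
    records.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
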