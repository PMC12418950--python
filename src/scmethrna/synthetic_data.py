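"""Seeded two-group single-cell multi-omic data generator.

Emulates the statistical structure of a two-group (in vitro matured vs in
vivo matured oocyte) single-cell study on a down-scaled genome: sparse
beta-binomial CpG methylomes at 0.5-3x-like coverage with a global CpG
methylation level near 47%, negative-binomial expression counts with
log-normal library sizes and a controlled mitochondrial fraction, planted
differentially methylated windows and differentially expressed genes with
known signs, and group-invariant imprinted gDMRs held near 0 or 1.

Every random draw is fixed by ``SimConfig.seed``; independent streams are
derived per component by stable hashing so adding one component never
perturbs another.

The generative model, per cell and 1-kb window: a window carries a latent
methylation level mu_w drawn from a Beta centered on ``baseline_meth``;
each cell draws a window-level fraction from a Beta with mean mu_w and
dispersion rho (``bb_dispersion``), shared by the CpGs of that window; each
CpG is captured independently with probability ``cpg_capture_rate``, gets
``1 + Poisson(coverage_mean - 1)`` reads, and a Binomial methylated-read
count.  Planted DMR windows shift mu_w by +-``dmr_delta`` in group 1 only.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneRecord,
    GenomicRegion,
    write_bed,
    write_bismark_cov,
    write_count_matrix,
    write_gene_table,
    write_results_table,
)
from .methylome_regions import gene_body_regions, promoter_regions, tile_windows

GROUP1 = "IVM"  # in vitro matured, low developmental competence
GROUP2 = "invivo"  # in vivo matured, high developmental competence


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component generator: seed fans out by stream name."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(stream.encode())])


@dataclass
class SimConfig:
    """Knobs of the synthetic study, with study-condition defaults.

    16 cells per group mirrors the sequencing arm of the study design;
    ``baseline_meth`` 0.47 matches the observed global CpG level of mature
    oocytes; sparse capture plus ~10 reads per covered CpG emulates
    low-coverage single-cell bisulfite data after CpG-dyad collapse.
    """

    seed: int = 0
    n_cells_per_group: int = 16
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 1000
    n_cgis: int = 150
    n_transposons: int = 80
    n_imprinted: int = 10
    baseline_meth: float = 0.47
    coverage_mean: float = 10.0
    cpg_capture_rate: float = 0.3
    bb_dispersion: float = 0.08
    n_dmrs_planted: int = 50
    dmr_delta: float = 0.4
    n_degs_planted: int = 150
    deg_log2fc: float = 2.5
    nb_dispersion: float = 0.3
    libsize_lognormal_sigma: float = 0.25
    mito_fraction: float = 0.02
    # placement / shape parameters of the down-scaled genome
    cpg_spacing: float = 80.0
    mu_concentration: float = 6.0
    gene_length_range: tuple[int, int] = (1000, 3000)
    gene_gap_range: tuple[int, int] = (200, 1200)
    cgi_promoter_fraction: float = 0.5
    window_width: int = 1000
    expr_log_mean: float = 1.5
    expr_log_sigma: float = 1.2

    def __post_init__(self) -> None:
        for name in ("baseline_meth", "cpg_capture_rate", "bb_dispersion",
                     "mito_fraction", "cgi_promoter_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_cells_per_group", "n_chrom", "chrom_length", "n_genes",
                     "n_cgis", "n_transposons", "n_imprinted", "n_dmrs_planted",
                     "n_degs_planted", "window_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if isinstance(self.gene_length_range, list):
            self.gene_length_range = tuple(self.gene_length_range)
        if isinstance(self.gene_gap_range, list):
            self.gene_gap_range = tuple(self.gene_gap_range)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def genome(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass
class TruthTable:
    """Ground truth of planted effects; ids reference the generated annotation."""

    groups: pd.DataFrame  # cell_id, group
    dmrs: pd.DataFrame | None = None  # region_id, delta (signed, group1 - group2)
    degs: pd.DataFrame | None = None  # gene_id, log2fc (signed, group1 vs group2)

    @property
    def group_labels(self) -> dict[str, str]:
        return dict(zip(self.groups["cell_id"], self.groups["group"]))


def cell_layout(config: SimConfig) -> pd.DataFrame:
    n = config.n_cells_per_group
    ids = [f"ivm_{i:02d}" for i in range(n)] + [f"vivo_{i:02d}" for i in range(n)]
    groups = [GROUP1] * n + [GROUP2] * n
    return pd.DataFrame({"cell_id": ids, "group": groups})


# ---------------------------------------------------------------------------
# annotation


def make_annotation(config: SimConfig) -> tuple[list[GeneRecord], list[GenomicRegion]]:
    """Place genes and genomic features on the synthetic genome.

    Gene bodies are non-overlapping with strand-aware TSS; promoters are the
    +-2 kb symmetric window around the TSS; a configurable fraction of CGIs
    sit on promoters and the rest in intergenic gaps, as do transposons;
    imprinted gDMRs are a subset of promoter CGIs flagged separately.
    """
    rng = stream_rng(config.seed, "annotation")
    lmin, lmax = config.gene_length_range
    gmin, gmax = config.gene_gap_range

    genes: list[GeneRecord] = []
    gaps: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}
    n_mito = max(3, config.n_genes // 200) if config.mito_fraction > 0 else 0
    mito_idx = set(rng.choice(config.n_genes, size=min(n_mito, config.n_genes),
                              replace=False).tolist()) if config.n_genes else set()
    gi = 0
    for chrom in config.chrom_names:
        cursor = int(rng.integers(gmin, gmax + 1))
        while gi < config.n_genes:
            length = int(rng.integers(lmin, lmax + 1))
            if cursor + length >= config.chrom_length:
                break
            start1 = cursor + 1  # 1-based inclusive
            end1 = cursor + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start1 if strand == "+" else end1
            genes.append(
                GeneRecord(f"gene_{gi:05d}", chrom, strand, tss, start1, end1,
                           is_mito=gi in mito_idx)
            )
            gap = int(rng.integers(gmin, gmax + 1))
            gaps[chrom].append((end1, min(end1 + gap, config.chrom_length)))
            cursor = end1 + gap
            gi += 1
        if gi >= config.n_genes:
            break
    if gi < config.n_genes:
        raise ValueError(
            f"genome too short: placed {gi} of {config.n_genes} genes on "
            f"{config.n_chrom} x {config.chrom_length} bp"
        )

    regions: list[GenomicRegion] = []
    regions.extend(promoter_regions(genes, flank=2000, chrom_sizes=config.genome))
    regions.extend(gene_body_regions(genes))

    # CGIs: a fraction on promoters (centered on TSS), the rest intergenic
    n_prom_cgi = int(round(config.cgi_promoter_fraction * config.n_cgis))
    n_prom_cgi = min(n_prom_cgi, len(genes))
    prom_gene_idx = rng.choice(len(genes), size=n_prom_cgi, replace=False)
    cgis: list[GenomicRegion] = []
    for k, idx in enumerate(sorted(prom_gene_idx.tolist())):
        g = genes[idx]
        half = int(rng.integers(200, 750))
        tss0 = g.tss - 1
        start = max(0, tss0 - half)
        end = min(config.chrom_length, tss0 + half)
        cgis.append(
            GenomicRegion(g.chrom, start, end, "CGI", f"cgi_prom_{k:04d}", gene_id=g.gene_id)
        )
    all_gaps = [(c, s, e) for c, iv in gaps.items() for s, e in iv if e - s >= 400]
    n_inter = config.n_cgis - n_prom_cgi
    if n_inter > 0:
        if not all_gaps:
            raise ValueError("no intergenic gaps wide enough to place CGIs")
        pick = rng.choice(len(all_gaps), size=n_inter, replace=len(all_gaps) < n_inter)
        for k, gidx in enumerate(pick.tolist()):
            chrom, s, e = all_gaps[gidx]
            width = min(e - s, int(rng.integers(300, 1200)))
            start = s + int(rng.integers(0, e - s - width + 1))
            cgis.append(
                GenomicRegion(chrom, start, start + width, "CGI", f"cgi_inter_{k:04d}")
            )
    regions.extend(cgis)

    # transposable elements: intergenic
    if config.n_transposons > 0:
        if not all_gaps:
            raise ValueError("no intergenic gaps wide enough to place transposons")
        pick = rng.choice(len(all_gaps), size=config.n_transposons,
                          replace=len(all_gaps) < config.n_transposons)
        for k, gidx in enumerate(pick.tolist()):
            chrom, s, e = all_gaps[gidx]
            width = min(e - s, int(rng.integers(300, 1000)))
            start = s + int(rng.integers(0, e - s - width + 1))
            regions.append(
                GenomicRegion(chrom, start, start + width, "transposon", f"te_{k:04d}")
            )

    # imprinted gDMRs: subset of promoter CGIs, re-tagged
    prom_cgis = [r for r in cgis if r.gene_id is not None]
    if config.n_imprinted > len(prom_cgis):
        raise ValueError(
            f"n_imprinted={config.n_imprinted} exceeds the {len(prom_cgis)} promoter CGIs"
        )
    if config.n_imprinted > 0:
        pick = rng.choice(len(prom_cgis), size=config.n_imprinted, replace=False)
        for k, idx in enumerate(sorted(pick.tolist())):
            r = prom_cgis[idx]
            regions.append(
                GenomicRegion(r.chrom, r.start, r.end, "imprinted_gDMR",
                              f"igDMR_{k:03d}", gene_id=r.gene_id)
            )
    return genes, regions


def regions_of_class(regions: Sequence[GenomicRegion], feature_class: str) -> list[GenomicRegion]:
    return [r for r in regions if r.feature_class == feature_class]


# ---------------------------------------------------------------------------
# methylomes


def simulate_methylomes(
    config: SimConfig,
    annotation: tuple[list[GeneRecord], list[GenomicRegion]],
) -> tuple[dict[str, pd.DataFrame], TruthTable]:
    """Draw per-cell CpG call frames plus the planted-DMR truth table.

    Returns cells as a mapping cell_id -> methylome frame (chrom, pos
    1-based, n_meth, n_unmeth), group 1 cells first.
    """
    _, regions = annotation
    rng = stream_rng(config.seed, "methylomes")
    layout = cell_layout(config)
    windows = tile_windows(config.genome, config.window_width)
    n_w = len(windows)

    conc = config.mu_concentration
    mu = rng.beta(config.baseline_meth * conc, (1 - config.baseline_meth) * conc, n_w)

    # window lookup: per chrom, window index = pos0 // width + offset
    offsets: dict[str, int] = {}
    off = 0
    for chrom, length in config.genome.items():
        offsets[chrom] = off
        off += -(-length // config.window_width)

    # imprinted gDMRs: mu pinned near 0 or 1, identical in both groups
    imprinted_windows: set[int] = set()
    for k, r in enumerate(regions_of_class(regions, "imprinted_gDMR")):
        level = 0.95 if k % 2 == 0 else 0.05
        w0 = offsets[r.chrom] + r.start // config.window_width
        w1 = offsets[r.chrom] + (r.end - 1) // config.window_width
        for w in range(w0, w1 + 1):
            mu[w] = level
            imprinted_windows.add(w)

    # planted DMR windows: signed shift in group 1
    mu_g1 = mu.copy()
    dmr_rows = []
    if config.n_dmrs_planted > 0:
        eligible = np.array(
            [w for w in range(n_w)
             if w not in imprinted_windows and 0.15 <= mu[w] <= 0.85]
        )
        if eligible.size < config.n_dmrs_planted:
            raise ValueError(
                f"only {eligible.size} windows eligible for {config.n_dmrs_planted} planted DMRs"
            )
        chosen = rng.choice(eligible, size=config.n_dmrs_planted, replace=False)
        # plant the full effect size: pick a random sign among the feasible
        # directions (both are feasible only for mid-range windows)
        coin = rng.random(config.n_dmrs_planted) < 0.5
        up_ok = mu[chosen] + config.dmr_delta <= 0.98
        down_ok = mu[chosen] - config.dmr_delta >= 0.02
        signs = np.where(up_ok & down_ok, np.where(coin, 1.0, -1.0),
                         np.where(up_ok, 1.0, -1.0))
        target = mu[chosen] + signs * config.dmr_delta
        clipped = np.clip(target, 0.02, 0.98)
        if np.any(clipped != target):
            warnings.warn(
                f"{int(np.sum(clipped != target))} planted DMR(s) clipped to [0.02, 0.98]",
                stacklevel=2,
            )
        mu_g1[chosen] = clipped
        for w, s in zip(chosen.tolist(), (clipped - mu[chosen]).tolist()):
            dmr_rows.append({"region_id": windows[w].region_id, "delta": s})

    # CpG site positions: exponential spacing, >= 2 bp
    chrom_arr, pos0_arr, widx_arr = [], [], []
    for chrom, length in config.genome.items():
        n_exp = int(length / config.cpg_spacing * 1.5) + 10
        spacing = np.maximum(2, np.round(rng.exponential(config.cpg_spacing, n_exp))).astype(np.int64)
        pos0 = np.cumsum(spacing)
        pos0 = pos0[pos0 < length]
        chrom_arr.append(np.full(pos0.size, chrom))
        pos0_arr.append(pos0)
        widx_arr.append(offsets[chrom] + pos0 // config.window_width)
    chroms = np.concatenate(chrom_arr)
    pos0 = np.concatenate(pos0_arr)
    widx = np.concatenate(widx_arr)
    n_sites = pos0.size

    rho = config.bb_dispersion
    mu_by_group = {GROUP1: np.clip(mu_g1, 0.005, 0.995), GROUP2: np.clip(mu, 0.005, 0.995)}
    cells: dict[str, pd.DataFrame] = {}
    for cell_id, group in zip(layout["cell_id"], layout["group"]):
        m = mu_by_group[group]
        if rho > 1e-9:
            a = m * (1 - rho) / rho
            b = (1 - m) * (1 - rho) / rho
            p_w = rng.beta(a, b)
        else:
            p_w = m
        captured = rng.random(n_sites) < config.cpg_capture_rate
        idx = np.flatnonzero(captured)
        cov = 1 + rng.poisson(config.coverage_mean - 1.0, idx.size)
        n_meth = rng.binomial(cov, p_w[widx[idx]])
        cells[cell_id] = pd.DataFrame(
            {
                "chrom": chroms[idx],
                "pos": pos0[idx] + 1,
                "n_meth": n_meth.astype(np.int64),
                "n_unmeth": (cov - n_meth).astype(np.int64),
            }
        )
    truth = TruthTable(
        groups=layout,
        dmrs=pd.DataFrame(dmr_rows, columns=["region_id", "delta"]),
    )
    return cells, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimConfig,
    annotation: tuple[list[GeneRecord], list[GenomicRegion]] | Sequence[GeneRecord],
) -> tuple[CountMatrix, TruthTable]:
    """Negative-binomial counts with planted DEGs and mitochondrial genes.

    Counts are Gamma-Poisson draws: mean = libsize_c x m_g (doubled or
    halved by the planted log2 fold change in group 1), dispersion
    ``nb_dispersion`` (variance mu + alpha mu^2).  Planted DEGs are drawn
    from non-mitochondrial genes with baseline mean at least
    max(10, median), so every planted effect acts on an expressed gene.
    """
    genes = annotation[0] if isinstance(annotation, tuple) else list(annotation)
    rng = stream_rng(config.seed, "expression")
    layout = cell_layout(config)
    n_genes, n_cells = len(genes), len(layout)

    m = rng.lognormal(config.expr_log_mean, config.expr_log_sigma, n_genes)
    is_mito = np.array([g.is_mito for g in genes])
    if is_mito.any() and config.mito_fraction > 0:
        target = config.mito_fraction / (1 - config.mito_fraction) * m[~is_mito].sum()
        m[is_mito] *= target / m[is_mito].sum()

    deg_rows = []
    m_g1 = m.copy()
    if config.n_degs_planted > 0:
        # plant on expressed genes (mean >= 10): a 2^2.5 effect on a nearly
        # silent gene is not a differential-abundance signal
        floor = max(10.0, float(np.median(m)))
        pool = np.flatnonzero(~is_mito & (m >= floor))
        if pool.size < config.n_degs_planted:
            raise ValueError(
                f"only {pool.size} genes eligible for {config.n_degs_planted} planted DEGs"
            )
        chosen = rng.choice(pool, size=config.n_degs_planted, replace=False)
        signs = np.where(np.arange(config.n_degs_planted) % 2 == 0, 1.0, -1.0)
        rng.shuffle(signs)
        m_g1[chosen] = m[chosen] * 2.0 ** (signs * config.deg_log2fc)
        for g, s in zip(chosen.tolist(), signs.tolist()):
            deg_rows.append({"gene_id": genes[g].gene_id, "log2fc": s * config.deg_log2fc})

    s_c = rng.lognormal(0.0, config.libsize_lognormal_sigma, n_cells)
    s_c /= np.exp(np.mean(np.log(s_c)))
    group1 = (layout["group"] == GROUP1).to_numpy()
    mean_mat = np.where(group1[None, :], m_g1[:, None], m[:, None]) * s_c[None, :]
    alpha = config.nb_dispersion
    if alpha > 1e-12:
        lam = rng.gamma(1.0 / alpha, mean_mat * alpha)
    else:
        lam = mean_mat
    counts = rng.poisson(lam)
    matrix = CountMatrix([g.gene_id for g in genes], layout["cell_id"].tolist(), counts)
    truth = TruthTable(
        groups=layout,
        degs=pd.DataFrame(deg_rows, columns=["gene_id", "log2fc"]),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# stylized fixtures for integration-stage tests


def simulate_block_multiomics(
    n_cells_per_group: int = 14,
    n_rna: int = 120,
    n_meth: int = 60,
    seed: int = 0,
    signal: float = 4.0,
    noise: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block-structured non-negative paired matrices for factorization tests.

    Each group activates a disjoint half of the RNA features and of the
    methylation loci (signal >> noise), the textbook case in which a K=2
    joint factorization must reproduce the group partition.  Returns
    (X_rna features x cells, X_meth loci x cells, group labels 0/1).
    """
    rng = stream_rng(seed, "block-multiomics")
    n_cells = 2 * n_cells_per_group
    labels = np.repeat([0, 1], n_cells_per_group)
    X_rna = rng.uniform(0, noise, size=(n_rna, n_cells))
    X_meth = rng.uniform(0, noise, size=(n_meth, n_cells))
    half_r, half_m = n_rna // 2, n_meth // 2
    for g in (0, 1):
        cells = labels == g
        rows_r = slice(0, half_r) if g == 0 else slice(half_r, n_rna)
        rows_m = slice(0, half_m) if g == 0 else slice(half_m, n_meth)
        X_rna[rows_r, cells] += rng.uniform(0.5 * signal, signal, size=(half_r, cells.sum()))
        X_meth[rows_m, cells] += rng.uniform(0.5 * signal, signal, size=(half_m, cells.sum()))
    return X_rna, X_meth, labels


def simulate_coupled_omics(
    config: SimConfig,
    n_loci: int = 120,
    n_pairs_planted: int = 20,
) -> dict:
    """Paired promoter-methylation / expression matrices with planted coupling.

    For ``n_pairs_planted`` (promoter locus, gene) pairs, cells of group 1
    share a latent factor that raises log-expression while lowering promoter
    methylation, producing a strong negative within-group-1 Pearson
    correlation; group 2 cells are uncoupled.  Unplanted pairs are noise in
    both groups.  Expression is returned on the log scale (the scale on
    which the pipeline correlates).
    """
    rng = stream_rng(config.seed, "coupled-omics")
    genes, _ = make_annotation(config)
    if n_loci > len(genes):
        raise ValueError(f"n_loci={n_loci} exceeds {len(genes)} genes")
    genes = genes[:n_loci]
    loci = promoter_regions(genes, flank=2000, chrom_sizes=config.genome)
    layout = cell_layout(config)
    g1 = (layout["group"] == GROUP1).to_numpy()
    n_cells = len(layout)

    expr = rng.normal(1.0, 0.5, size=(n_loci, n_cells))
    mu_l = rng.beta(2.0, 2.0, n_loci)
    meth = np.clip(mu_l[:, None] + rng.normal(0, 0.08, size=(n_loci, n_cells)), 0.01, 0.99)

    if n_pairs_planted > n_loci:
        raise ValueError("n_pairs_planted exceeds n_loci")
    planted = rng.choice(n_loci, size=n_pairs_planted, replace=False)
    for i in planted.tolist():
        z = rng.normal(0, 1, int(g1.sum()))
        expr[i, g1] = 1.0 + 0.8 * z + rng.normal(0, 0.1, int(g1.sum()))
        meth[i, g1] = np.clip(0.5 - 0.18 * z + rng.normal(0, 0.03, int(g1.sum())), 0.01, 0.99)
    truth = pd.DataFrame(
        {
            "locus_id": [loci[i].region_id for i in planted.tolist()],
            "gene_id": [genes[i].gene_id for i in planted.tolist()],
            "group": GROUP1,
            "sign": "negative",
        }
    )
    cell_ids = layout["cell_id"].tolist()
    return {
        "meth": pd.DataFrame(meth, index=[r.region_id for r in loci], columns=cell_ids),
        "expr": pd.DataFrame(expr, index=[g.gene_id for g in genes], columns=cell_ids),
        "loci": loci,
        "genes": genes,
        "groups": layout,
        "truth_pairs": truth,
    }


# ---------------------------------------------------------------------------
# on-disk dataset


def write_dataset(config: SimConfig, outdir: str | Path) -> dict[str, object]:
    """Generate and write a complete dataset in the formats the readers expect.

    Writes per-cell ``.cov.gz`` methylomes, the gene table, BED files per
    feature class, the count matrix, the truth tables, and the group
    assignment.  Returns a manifest of paths.
    """
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    genes, regions = make_annotation(config)
    cells, meth_truth = simulate_methylomes(config, (genes, regions))
    counts, expr_truth = simulate_expression(config, genes)

    cov_paths = {}
    for cell_id, frame in cells.items():
        p = outdir / "cells" / f"{cell_id}.cov.gz"
        write_bismark_cov(frame, p)
        cov_paths[cell_id] = str(p)
    write_gene_table(genes, outdir / "genes.tsv")
    for cls, fname in (("CGI", "cgis.bed"), ("transposon", "transposons.bed"),
                       ("imprinted_gDMR", "imprinted.bed")):
        write_bed(regions_of_class(regions, cls), outdir / fname)
    write_count_matrix(counts, outdir / "counts.tsv")
    write_results_table(meth_truth.groups, outdir / "groups.tsv")
    write_results_table(meth_truth.dmrs, outdir / "truth_dmrs.tsv")
    write_results_table(expr_truth.degs, outdir / "truth_degs.tsv")
    return {
        "cells": cov_paths,
        "genes": str(outdir / "genes.tsv"),
        "beds": {c: str(outdir / f) for c, f in
                 (("CGI", "cgis.bed"), ("transposon", "transposons.bed"),
                  ("imprinted_gDMR", "imprinted.bed"))},
        "counts": str(outdir / "counts.tsv"),
        "groups": str(outdir / "groups.tsv"),
        "truth_dmrs": str(outdir / "truth_dmrs.tsv"),
        "truth_degs": str(outdir / "truth_degs.tsv"),
        "config": asdict(config),
    }
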