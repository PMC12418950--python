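"""End-to-end orchestration: simulate -> qc -> regions -> dmr -> deg ->
integrate -> report, from one validated config.

Each stage is a function that reads its inputs from the run directory and
writes TSV outputs there, so stages can be re-run individually from the
CLI.  ``run_all`` sequences them and writes a manifest with per-stage
output checksums; rerunning with an identical config reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import de_caller, dm_caller, integration, qc_filters
from .config import sim_config_from
from .io_formats import (
    GenomicRegion,
    calls_to_frame,
    read_bed,
    read_bismark_cov,
    read_count_matrix,
    read_gene_table,
    read_results_table,
    write_results_table,
)
from .methylome_regions import (
    RegionMethylationMatrix,
    aggregate_region,
    detect_vmrs,
    gene_body_regions,
    imprint_report,
    promoter_regions,
    tile_windows,
)
from .synthetic_data import write_dataset

log = logging.getLogger("scmethrna")

FEATURE_CLASS_FILES = {"CGI": "cgis.bed", "transposon": "transposons.bed",
                       "imprinted_gDMR": "imprinted.bed"}
DM_CLASSES = ["CGI", "promoter", "gene_body", "transposon", "window1kb"]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# data loading


def _data_dir(cfg: Mapping[str, Any], outdir: Path) -> Path:
    if cfg["sim"]["enabled"]:
        return outdir / "data"
    data_dir = cfg["paths"]["data_dir"]
    if not data_dir:
        raise ValueError("sim disabled and no paths.data_dir configured")
    p = Path(data_dir)
    if not p.exists():
        raise FileNotFoundError(f"input path does not exist: {p}")
    return p


def load_dataset(data_dir: str | Path) -> dict[str, Any]:
    data_dir = Path(data_dir)
    for required in ("genes.tsv", "counts.tsv", "groups.tsv"):
        if not (data_dir / required).exists():
            raise FileNotFoundError(f"missing input file: {data_dir / required}")
    cells = {}
    for p in sorted((data_dir / "cells").glob("*.cov*")):
        cell_id = p.name.split(".cov")[0]
        cells[cell_id] = calls_to_frame(read_bismark_cov(p))
    genes = read_gene_table(data_dir / "genes.tsv")
    beds = {}
    for cls, fname in FEATURE_CLASS_FILES.items():
        p = data_dir / fname
        beds[cls] = read_bed(p, cls) if p.exists() else []
    counts = read_count_matrix(data_dir / "counts.tsv")
    groups_df = read_results_table(data_dir / "groups.tsv")
    groups = dict(zip(groups_df["cell_id"].astype(str), groups_df["group"].astype(str)))
    return {"cells": cells, "genes": genes, "beds": beds, "counts": counts,
            "groups": groups}


def _infer_genome(cfg: Mapping[str, Any], cells: Mapping[str, pd.DataFrame]) -> dict[str, int]:
    if cfg["sim"]["enabled"]:
        sim = sim_config_from(cfg)
        return sim.genome
    genome: dict[str, int] = {}
    for df in cells.values():
        for chrom, sub in df.groupby("chrom"):
            genome[str(chrom)] = max(genome.get(str(chrom), 0), int(sub["pos"].max()))
    return genome


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: Mapping[str, Any], outdir: Path) -> list[Path]:
    sim = sim_config_from(cfg)
    write_dataset(sim, outdir / "data")
    return sorted((outdir / "data").rglob("*.*"))


def stage_qc(cfg: Mapping[str, Any], outdir: Path) -> list[Path]:
    data = load_dataset(_data_dir(cfg, outdir))
    rna_qc = qc_filters.rna_cell_qc(data["counts"], data["genes"])
    kept_rna, rna_report = qc_filters.filter_rna_cells(
        rna_qc, qc_filters.RnaQcThresholds(**cfg["qc"]["rna"])
    )
    bs_qc = qc_filters.bs_cell_qc(data["cells"])
    kept_bs, bs_report = qc_filters.filter_bs_cells(
        bs_qc, qc_filters.BsQcThresholds(**cfg["qc"]["bs"])
    )
    outputs = []
    for name, obj in (("qc_rna.tsv", rna_report), ("qc_bs.tsv", bs_report)):
        write_results_table(obj, outdir / name)
        outputs.append(outdir / name)
    for name, kept in (("kept_cells_rna.txt", kept_rna), ("kept_cells_bs.txt", kept_bs)):
        (outdir / name).write_text("".join(f"{c}\n" for c in kept))
        outputs.append(outdir / name)
    log.info("qc: kept %d/%d RNA cells, %d/%d BS cells",
             len(kept_rna), len(rna_report), len(kept_bs), len(bs_report))
    return outputs


def _kept(outdir: Path, name: str) -> list[str]:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(f"missing QC output {p}; run the qc stage first")
    return [ln for ln in p.read_text().splitlines() if ln]


def _build_region_sets(cfg, data, genome) -> dict[str, list[GenomicRegion]]:
    flank = cfg["regions"]["promoter_flank"]
    sets = {
        "promoter": promoter_regions(data["genes"], flank=flank, chrom_sizes=genome),
        "gene_body": gene_body_regions(data["genes"]),
        "window1kb": tile_windows(genome, cfg["regions"]["window_width"]),
    }
    sets.update({cls: regs for cls, regs in data["beds"].items()})
    return sets


def _write_region_matrix(mat: RegionMethylationMatrix, outdir: Path, cls: str) -> list[Path]:
    meta = pd.DataFrame(
        [(r.region_id, r.chrom, r.start, r.end, r.feature_class, r.gene_id or "")
         for r in mat.regions],
        columns=["region_id", "chrom", "start", "end", "feature_class", "gene_id"],
    )
    paths = []
    for suffix, frame in (
        ("meta", meta),
        ("fraction", mat.to_frame().rename_axis("region_id").reset_index()),
        ("ncpg", pd.DataFrame(mat.n_cpgs_covered, index=mat.region_ids,
                              columns=mat.cell_ids).rename_axis("region_id").reset_index()),
        ("reads", pd.DataFrame(mat.total_reads, index=mat.region_ids,
                               columns=mat.cell_ids).rename_axis("region_id").reset_index()),
    ):
        p = outdir / f"regions_{cls}.{suffix}.tsv"
        write_results_table(frame, p)
        paths.append(p)
    return paths


def _read_region_matrix(outdir: Path, cls: str) -> RegionMethylationMatrix:
    meta = read_results_table(outdir / f"regions_{cls}.meta.tsv")
    frac = read_results_table(outdir / f"regions_{cls}.fraction.tsv").set_index("region_id")
    ncpg = read_results_table(outdir / f"regions_{cls}.ncpg.tsv").set_index("region_id")
    reads = read_results_table(outdir / f"regions_{cls}.reads.tsv").set_index("region_id")
    regions = [
        GenomicRegion(str(r.chrom), int(r.start), int(r.end), str(r.feature_class),
                      str(r.region_id), gene_id=(str(r.gene_id) if isinstance(r.gene_id, str) and r.gene_id else None))
        for r in meta.itertuples(index=False)
    ]
    return RegionMethylationMatrix(
        regions, [str(c) for c in frac.columns], frac.to_numpy(float),
        ncpg.to_numpy(np.int64), reads.to_numpy(np.int64),
    )


def stage_regions(cfg: Mapping[str, Any], outdir: Path) -> list[Path]:
    data = load_dataset(_data_dir(cfg, outdir))
    kept_bs = _kept(outdir, "kept_cells_bs.txt")
    cells = {c: data["cells"][c] for c in kept_bs}
    genome = _infer_genome(cfg, cells)
    region_sets = _build_region_sets(cfg, data, genome)
    min_cov = cfg["regions"]["min_cov_per_cpg"]
    pooling = cfg["regions"]["pooling"]
    outputs = []
    matrices = {}
    for cls, regions in region_sets.items():
        if not regions:
            continue
        mat = aggregate_region(cells, regions, min_cov_per_cpg=min_cov, pooling=pooling)
        matrices[cls] = mat
        outputs.extend(_write_region_matrix(mat, outdir, cls))
    # VMRs from the window matrix, then their own aggregated matrix
    if "window1kb" in matrices:
        vmrs = detect_vmrs(matrices["window1kb"], cfg["regions"]["vmr_top_fraction"],
                           cfg["regions"]["vmr_min_cells"])
        vmr_regions = [v.region for v in vmrs]
        if vmr_regions:
            mat = aggregate_region(cells, vmr_regions, min_cov_per_cpg=min_cov,
                                   pooling=pooling)
            outputs.extend(_write_region_matrix(mat, outdir, "VMR"))
        vmr_table = pd.DataFrame(
            [(v.region.region_id, v.region.chrom, v.region.start, v.region.end,
              v.variance_across_cells, v.rank, v.n_windows) for v in vmrs],
            columns=["region_id", "chrom", "start", "end", "variance", "rank", "n_windows"],
        )
        write_results_table(vmr_table, outdir / "vmrs.tsv")
        outputs.append(outdir / "vmrs.tsv")
    # imprinted stability report
    if "imprinted_gDMR" in matrices:
        rep = imprint_report(matrices["imprinted_gDMR"], data["groups"],
                             cfg["regions"]["imprint_tolerance"])
        write_results_table(rep, outdir / "imprint_report.tsv")
        outputs.append(outdir / "imprint_report.tsv")
    return outputs


def stage_dmr(cfg: Mapping[str, Any], outdir: Path) -> list[Path]:
    data = load_dataset(_data_dir(cfg, outdir))
    dm_cfg = dm_caller.DmFilterConfig(
        min_cov_per_cpg=cfg["regions"]["min_cov_per_cpg"], **cfg["dmr"]
    )
    outputs = []
    all_results = []
    for cls in DM_CLASSES:
        if not (outdir / f"regions_{cls}.meta.tsv").exists():
            continue
        mat = _read_region_matrix(outdir, cls)
        results = dm_caller.call_dmrs(mat, data["groups"], dm_cfg)
        all_results.extend(results)
        frame = dm_caller.results_to_frame(results)
        p = outdir / f"dmr_{cls}.tsv"
        write_results_table(frame, p)
        outputs.append(p)
    summary = dm_caller.summarize_dmrs(all_results)
    write_results_table(summary, outdir / "dmr_summary.tsv")
    outputs.append(outdir / "dmr_summary.tsv")
    return outputs


def stage_deg(cfg: Mapping[str, Any], outdir: Path) -> list[Path]:
    data = load_dataset(_data_dir(cfg, outdir))
    kept = _kept(outdir, "kept_cells_rna.txt")
    counts = data["counts"]
    col = [counts.cell_ids.index(c) for c in kept]
    sub = counts.counts[:, col]
    groups = data["groups"]
    g1_mask = np.array([groups[c] == "IVM" for c in kept])
    factors = de_caller.size_factors(sub)
    d = cfg["deg"]
    res = de_caller.nb_test(
        sub, g1_mask, factors,
        de_caller.NbTestConfig(pseudocount=d["pseudocount"],
                               dispersion_shrinkage=d["dispersion_shrinkage"],
                               min_cells_expressed=d["min_cells_expressed"]),
    )
    table, summary = de_caller.call_degs(res, counts.gene_ids, d["alpha"], d["lfc_min"])
    hvg = de_caller.select_hvg(sub, counts.gene_ids, n=min(d["n_hvg"], len(counts.gene_ids)),
                               factors=factors)
    n_pcs = min(d["n_pcs"], len(hvg), len(kept) - 1)
    scores = de_caller.pca_embed(sub, counts.gene_ids, hvg, n_pcs, factors)
    outputs = []
    write_results_table(table, outdir / "deg_results.tsv")
    write_results_table(pd.DataFrame([summary]), outdir / "deg_summary.tsv")
    (outdir / "hvg.txt").write_text("".join(f"{g}\n" for g in hvg))
    pca_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    pca_df.insert(0, "cell_id", kept)
    write_results_table(pca_df, outdir / "pca_scores.tsv")
    outputs += [outdir / n for n in
                ("deg_results.tsv", "deg_summary.tsv", "hvg.txt", "pca_scores.tsv")]
    log.info("deg: %d up, %d down", summary["n_up"], summary["n_down"])
    return outputs


def stage_integrate(cfg: Mapping[str, Any], outdir: Path) -> list[Path]:
    data = load_dataset(_data_dir(cfg, outdir))
    kept_rna = _kept(outdir, "kept_cells_rna.txt")
    kept_bs = _kept(outdir, "kept_cells_bs.txt")
    shared = [c for c in kept_rna if c in set(kept_bs)]
    icfg = cfg["integration"]
    if len(shared) < icfg["K"]:
        raise ValueError(f"only {len(shared)} cells pass QC in both omics")

    # methylation layer: promoters + CGIs + VMRs on the shared cells
    mats, loci = [], []
    for cls in ("promoter", "CGI", "VMR"):
        p = outdir / f"regions_{cls}.meta.tsv"
        if not p.exists():
            continue
        mat = _read_region_matrix(outdir, cls)
        cols = [mat.cell_ids.index(c) for c in shared]
        mats.append(pd.DataFrame(mat.meth_fraction[:, cols],
                                 index=mat.region_ids, columns=shared))
        loci.extend(mat.regions)
    meth = pd.concat(mats, axis=0)
    keep_rows = ~meth.index.duplicated()
    meth = meth.loc[keep_rows]
    seen = set()
    loci = [r for r in loci if not (r.region_id in seen or seen.add(r.region_id))]

    counts = data["counts"]
    col = [counts.cell_ids.index(c) for c in shared]
    sub = counts.counts[:, col]
    factors = de_caller.size_factors(sub)
    log_expr = pd.DataFrame(np.log1p(sub / factors[None, :]),
                            index=counts.gene_ids, columns=shared)
    hvg_path = outdir / "hvg.txt"
    hvg = [g for g in hvg_path.read_text().splitlines() if g] if hvg_path.exists() \
        else list(log_expr.index)
    X_rna = log_expr.loc[hvg].to_numpy()
    X_meth = integration.impute_missing_mean(meth.to_numpy())

    from .synthetic_data import stream_rng

    nmf_seed = int(stream_rng(cfg["seed"], "joint-nmf").integers(2**31))
    model = integration.joint_nmf(X_rna, X_meth, shared, K=icfg["K"],
                                  seed=nmf_seed, max_iter=icfg["max_iter"],
                                  tol=icfg["tol"], lam=icfg["lam"])
    markers_rna = integration.rank_factor_markers(model, X_rna, hvg,
                                                  icfg["marker_alpha"], icfg["marker_min_fc"])
    markers_meth = integration.rank_factor_markers(model, X_meth, list(meth.index),
                                                   icfg["marker_alpha"], icfg["marker_min_fc"])
    corr_cfg = integration.CorrelationConfig(
        max_distance=icfg["max_distance"], min_abs_r=icfg["min_abs_r"],
        min_r_diff=icfg["min_r_diff"], guard_r=icfg["guard_r"],
        min_pairs=icfg["min_pairs"],
    )
    records, corr_summary = integration.correlate_meth_expr(
        meth, loci, log_expr, data["genes"], data["groups"], corr_cfg
    )
    factors_df = pd.DataFrame(model.H.T, columns=[f"factor_{k+1}" for k in range(model.n_factors)])
    factors_df.insert(0, "cell_id", shared)
    factors_df["factor_assignment"] = model.factor_assignment
    outputs = []
    for name, frame in (("factors.tsv", factors_df), ("markers_rna.tsv", markers_rna),
                        ("markers_meth.tsv", markers_meth), ("correlations.tsv", records),
                        ("correlation_summary.tsv", corr_summary)):
        write_results_table(frame, outdir / name)
        outputs.append(outdir / name)
    return outputs


def stage_report(cfg: Mapping[str, Any], outdir: Path) -> list[Path]:
    lines = ["scmethrna run report", "===================", ""]

    def table(name):
        p = outdir / name
        if not p.exists():
            return None
        try:
            return read_results_table(p)
        except Exception as exc:  # pragma: no cover - corrupted output
            raise ValueError(f"report: could not parse {name} (stage output corrupted): {exc}")

    qc_rna, qc_bs = table("qc_rna.tsv"), table("qc_bs.tsv")
    if qc_rna is not None:
        lines.append(f"RNA cells passing QC: {int(qc_rna['pass'].sum())} / {len(qc_rna)}")
    if qc_bs is not None:
        lines.append(f"BS cells passing QC: {int(qc_bs['pass'].sum())} / {len(qc_bs)}")
    dmr = table("dmr_summary.tsv")
    if dmr is not None:
        total = int(dmr["n_significant"].sum())
        lines.append(f"DMRs called: {total}" + (" (zero DMRs detected)" if total == 0 else ""))
        for r in dmr.itertuples(index=False):
            lines.append(
                f"  {r.feature_class}: {r.n_significant} significant "
                f"(g1 hypo/hyper {r.n_hypo_g1}/{r.n_hyper_g1}, "
                f"g2 hypo/hyper {r.n_hypo_g2}/{r.n_hyper_g2})"
            )
    deg = table("deg_summary.tsv")
    if deg is not None:
        r = deg.iloc[0]
        lines.append(f"DEGs: {int(r['n_total'])} ({int(r['n_up'])} up, {int(r['n_down'])} down in group 1)")
    fac = table("factors.tsv")
    if fac is not None:
        n_factors = sum(c.startswith("factor_") and c.removeprefix("factor_").isdigit()
                        for c in fac.columns)
        lines.append(f"Integration: {n_factors} factors over {len(fac)} cells")
        counts = fac["factor_assignment"].value_counts().sort_index()
        for k, n in counts.items():
            lines.append(f"  factor {k}: {n} cells")
    corr = table("correlation_summary.tsv")
    if corr is not None:
        for r in corr.itertuples(index=False):
            lines.append(
                f"Correlations [{r.group}]: {r.n_records} "
                f"({r.n_positive} positive, {r.n_negative} negative)"
            )
    imp = table("imprint_report.tsv")
    if imp is not None:
        lines.append(
            f"Imprinted gDMRs stable across groups: {int(imp['appropriate'].sum())} / {len(imp)}"
        )
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return [outdir / "report.txt"]


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "regions": stage_regions,
    "dmr": stage_dmr,
    "deg": stage_deg,
    "integrate": stage_integrate,
    "report": stage_report,
}


def run_all(cfg: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run every stage in order and write a checksummed manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    order = ["simulate", "qc", "regions", "dmr", "deg", "integrate", "report"]
    if not cfg["sim"]["enabled"]:
        order = order[1:]
    manifest: dict[str, Any] = {"seed": cfg["seed"], "stages": {}}
    t0 = time.time()
    for stage in order:
        t = time.time()
        try:
            outputs = STAGES[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t, 2),
            "outputs": {str(p.relative_to(outdir)): sha256_file(p) for p in outputs},
        }
        log.info("stage %s done in %.1fs (%d outputs)", stage,
                 time.time() - t, len(outputs))
    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
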