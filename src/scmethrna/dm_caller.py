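"""Differential-methylation caller: filter cascade, t-test, classification.

The caller reproduces a three-rule filtering script for region-level
single-cell bisulfite data:

1. only CpGs with at least ``min_cov_per_cpg`` reads contribute to a
   region's methylation estimate (applied upstream, in
   :func:`~scmethrna.methylome_regions.aggregate_region`);
2. a region is kept only if at least half of the cells in EACH group have
   reads in it;
3. a region is kept only if the average region read count over
   contributing cells is strictly greater than ``min_mean_reads_per_group``
   in EACH group.

Retained regions are compared between groups with a two-sample t-test
(Welch by default, matching R's ``t.test`` default; pooled Student
available).  A region is a DMR when p < alpha and the absolute group
difference in methylation fraction exceeds ``min_delta`` (the ">10
percentage points" reading of "FC > 0.1").  Each group additionally gets a
methylation-level label: hypermethylated above ``hyper_threshold`` (75%),
hypomethylated below ``hypo_threshold`` (25%), intermediate otherwise.  No
multiple-testing correction is applied by default (raw p < .05); a BH
option exists for sensitivity analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicRegion
from .methylome_regions import RegionMethylationMatrix


@dataclass(frozen=True)
class DmFilterConfig:
    min_cov_per_cpg: int = 5
    min_cell_fraction_per_group: float = 0.5
    min_mean_reads_per_group: float = 10.0
    alpha: float = 0.05
    min_delta: float = 0.1
    hyper_threshold: float = 0.75
    hypo_threshold: float = 0.25
    test_variant: str = "welch"  # R t.test default is unequal-variance
    rule3_mode: str = "region_reads"  # or "per_cpg_coverage"
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.hypo_threshold >= self.hyper_threshold:
            raise ValueError("hypo_threshold must be < hyper_threshold")
        if self.test_variant not in ("welch", "student"):
            raise ValueError(f"unknown test_variant {self.test_variant!r}")
        if self.rule3_mode not in ("region_reads", "per_cpg_coverage"):
            raise ValueError(f"unknown rule3_mode {self.rule3_mode!r}")


@dataclass
class DmrResult:
    region: GenomicRegion
    mean_g1: float
    mean_g2: float
    delta: float
    p_value: float
    significant: bool
    level_label_g1: str
    level_label_g2: str
    n_cells_g1: int
    n_cells_g2: int
    status: str = "tested"  # or "untested:<reason>"


def _group_masks(
    cell_ids: Sequence[str], groups: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray, str, str]:
    labels = [groups[c] for c in cell_ids]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    # group 1 = the treatment-like label when recognizable, else first sorted
    g1 = "IVM" if "IVM" in uniq else uniq[0]
    g2 = [u for u in uniq if u != g1][0]
    m1 = np.array([l == g1 for l in labels])
    return m1, ~m1, g1, g2


def dm_filter_cascade(
    matrix: RegionMethylationMatrix,
    groups: Mapping[str, str],
    cfg: DmFilterConfig = DmFilterConfig(),
) -> tuple[np.ndarray, dict[str, int]]:
    """Apply rules 2 and 3 (rule 1 lives in the aggregation step).

    Returns indices of retained regions plus per-rule drop counts; rule 2
    is evaluated before rule 3, so a region failing both is charged to
    rule 2.
    """
    m1, m2, _, _ = _group_masks(matrix.cell_ids, groups)
    frac = matrix.meth_fraction
    reads = matrix.total_reads.astype(float)
    present = ~np.isnan(frac)

    need1 = math.ceil(cfg.min_cell_fraction_per_group * int(m1.sum()))
    need2 = math.ceil(cfg.min_cell_fraction_per_group * int(m2.sum()))
    rule2_ok = (present[:, m1].sum(axis=1) >= need1) & (present[:, m2].sum(axis=1) >= need2)

    if cfg.rule3_mode == "region_reads":
        stat = reads
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(matrix.n_cpgs_covered > 0, reads / matrix.n_cpgs_covered, np.nan)

    def group_mean_reads(mask: np.ndarray) -> np.ndarray:
        pres = present[:, mask]
        vals = np.where(pres, stat[:, mask], 0.0)
        n = pres.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, vals.sum(axis=1) / n, 0.0)

    rule3_ok = (group_mean_reads(m1) > cfg.min_mean_reads_per_group) & (
        group_mean_reads(m2) > cfg.min_mean_reads_per_group
    )
    retained = np.flatnonzero(rule2_ok & rule3_ok)
    drops = {
        "rule2": int(np.sum(~rule2_ok)),
        "rule3": int(np.sum(rule2_ok & ~rule3_ok)),
    }
    return retained, drops


def dm_test(
    fractions_g1: Sequence[float],
    fractions_g2: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided two-sample t-test on methylation fractions.

    ``welch`` uses unequal variances with Welch-Satterthwaite df (the
    default behavior of R's ``t.test``); ``student`` pools the variance
    with df n1 + n2 - 2.  Degenerate zero-variance-in-both-groups input
    returns t=0, p=1 when the means are equal.
    """
    x = np.asarray(fractions_g1, dtype=float)
    y = np.asarray(fractions_g2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def _level_label(mean: float, cfg: DmFilterConfig) -> str:
    if mean > cfg.hyper_threshold:
        return "hyper"
    if mean < cfg.hypo_threshold:
        return "hypo"
    return "intermediate"


def call_dmrs(
    matrix: RegionMethylationMatrix,
    groups: Mapping[str, str],
    cfg: DmFilterConfig = DmFilterConfig(),
    cascade_applied: bool = False,
) -> list[DmrResult]:
    """Run the full caller on a region matrix.

    Unless ``cascade_applied``, the filter cascade runs first.  Regions in
    which a group has fewer than two covered cells are reported with an
    ``untested`` status rather than silently dropped.
    """
    if not cascade_applied:
        retained, _ = dm_filter_cascade(matrix, groups, cfg)
        matrix = matrix.subset_regions(retained)
    m1, m2, _, _ = _group_masks(matrix.cell_ids, groups)
    results: list[DmrResult] = []
    p_values = []
    for i, region in enumerate(matrix.regions):
        row = matrix.meth_fraction[i]
        x = row[m1]
        y = row[m2]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        mean1 = float(np.mean(x)) if x.size else float("nan")
        mean2 = float(np.mean(y)) if y.size else float("nan")
        delta = mean1 - mean2
        if x.size < 2 or y.size < 2:
            results.append(
                DmrResult(region, mean1, mean2, delta, float("nan"), False,
                          _level_label(mean1, cfg) if x.size else "na",
                          _level_label(mean2, cfg) if y.size else "na",
                          int(x.size), int(y.size),
                          status="untested:<2 covered cells in a group")
            )
            p_values.append(np.nan)
            continue
        t, p = dm_test(x, y, cfg.test_variant)
        results.append(
            DmrResult(region, mean1, mean2, delta, p, False,
                      _level_label(mean1, cfg), _level_label(mean2, cfg),
                      int(x.size), int(y.size))
        )
        p_values.append(p)
    p_arr = np.array(p_values)
    if cfg.bh_correct:
        from .de_caller import bh_fdr

        p_arr = bh_fdr(p_arr)
    for r, p in zip(results, p_arr):
        if r.status == "tested":
            r.significant = bool(p < cfg.alpha and abs(r.delta) > cfg.min_delta)
    return results


def results_to_frame(results: Sequence[DmrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region.region_id,
                "feature_class": r.region.feature_class,
                "chrom": r.region.chrom,
                "start": r.region.start,
                "end": r.region.end,
                "mean_g1": r.mean_g1,
                "mean_g2": r.mean_g2,
                "delta": r.delta,
                "p_value": r.p_value,
                "significant": r.significant,
                "level_label_g1": r.level_label_g1,
                "level_label_g2": r.level_label_g2,
                "n_cells_g1": r.n_cells_g1,
                "n_cells_g2": r.n_cells_g2,
                "status": r.status,
            }
            for r in results
        ]
    )


def hypo_fraction_percent(n_hypo: int, n_labeled: int) -> int:
    """Percent of labeled DMRs that are hypomethylated, half-up to integer."""
    if n_labeled == 0:
        return 0
    import decimal

    pct = decimal.Decimal(100 * n_hypo) / decimal.Decimal(n_labeled)
    return int(pct.quantize(decimal.Decimal("1"), rounding=decimal.ROUND_HALF_UP))


def summarize_dmrs(results: Sequence[DmrResult]) -> pd.DataFrame:
    """Per-feature-class DMR counts and hyper/hypo breakdown.

    A DMR is counted "hypomethylated in group k" when group k's own mean
    puts it below the hypo threshold; the hypo percentage is taken among
    the group's labeled (hyper or hypo) DMRs.
    """
    classes = sorted({r.region.feature_class for r in results})
    rows = []
    for cls in classes:
        sub = [r for r in results if r.region.feature_class == cls]
        sig = [r for r in sub if r.significant]
        hyper1 = sum(r.level_label_g1 == "hyper" for r in sig)
        hypo1 = sum(r.level_label_g1 == "hypo" for r in sig)
        hyper2 = sum(r.level_label_g2 == "hyper" for r in sig)
        hypo2 = sum(r.level_label_g2 == "hypo" for r in sig)
        rows.append(
            {
                "feature_class": cls,
                "n_tested": sum(r.status == "tested" for r in sub),
                "n_significant": len(sig),
                "n_hyper_g1": hyper1,
                "n_hypo_g1": hypo1,
                "n_hyper_g2": hyper2,
                "n_hypo_g2": hypo2,
                "pct_hypo_g1": hypo_fraction_percent(hypo1, hypo1 + hyper1),
                "pct_hypo_g2": hypo_fraction_percent(hypo2, hypo2 + hyper2),
            }
        )
    columns = ["feature_class", "n_tested", "n_significant", "n_hyper_g1",
               "n_hypo_g1", "n_hyper_g2", "n_hypo_g2", "pct_hypo_g1", "pct_hypo_g2"]
    return pd.DataFrame(rows, columns=columns)
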