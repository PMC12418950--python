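"""Two-group negative-binomial differential expression for count matrices.

A transparent from-scratch NB engine: median-of-ratios size factors,
method-of-moments gene dispersions shrunk toward a mean-dispersion trend,
a Wald test on the log ratio of size-factor-normalized group means with a
delta-method standard error from the NB variance function (mu + alpha
mu^2), Benjamini-Hochberg FDR, and the study thresholds (FDR < 0.05 and
|log2FC| >= 2) for calling genes up/down.  The Wald statistic is referred
to a t distribution with n1 + n2 - 2 df, which keeps null p-values uniform
at the ~30-cell scale of this design.

Also provides highly-variable-gene selection (standardized variance against
a binned-median mean-variance trend) and a deterministic PCA embedding for
visualization; those feed embeddings only, never the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, geometric mean 1.

    Ratios are taken against the per-gene geometric mean, restricted to
    genes expressed in every cell; when no such gene exists the factors
    fall back to relative library sizes (with a warning).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be genes x cells")
    n_cells = counts.shape[1]
    if n_cells == 1:
        return np.ones(1)
    all_expressed = (counts > 0).all(axis=1)
    if not all_expressed.any():
        warnings.warn(
            "no gene expressed in all cells; falling back to library-size factors",
            stacklevel=2,
        )
        libs = counts.sum(axis=0)
        if np.any(libs == 0):
            raise ValueError("cell with zero total counts")
        factors = libs
    else:
        sub = counts[all_expressed]
        log_geomean = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def select_hvg(
    counts: np.ndarray,
    gene_ids: Sequence[str],
    n: int = 2000,
    factors: np.ndarray | None = None,
    n_bins: int = 20,
) -> list[str]:
    """Top-n genes by standardized variance of log1p normalized counts.

    The raw log1p variance is divided by a mean-variance trend (median
    variance within mean-expression bins), so highly expressed genes do not
    dominate.  Ties break deterministically by gene id.
    """
    counts = np.asarray(counts, dtype=float)
    if n > counts.shape[0]:
        warnings.warn(f"n={n} exceeds {counts.shape[0]} genes; returning all", stacklevel=2)
        n = counts.shape[0]
    if factors is None:
        factors = size_factors(counts)
    log_norm = np.log1p(counts / factors[None, :])
    mean = log_norm.mean(axis=1)
    var = log_norm.var(axis=1, ddof=1) if counts.shape[1] > 1 else np.zeros_like(mean)

    # binned-median trend over mean expression; constant genes stay at 0
    order = np.argsort(mean, kind="stable")
    trend = np.ones_like(var)
    bins = np.array_split(order, min(n_bins, max(1, len(order) // 5) or 1))
    for b in bins:
        if b.size == 0:
            continue
        med = np.median(var[b])
        trend[b] = med if med > 0 else 1.0
    std_var = var / trend
    key = sorted(range(len(gene_ids)), key=lambda i: (-std_var[i], str(gene_ids[i])))
    return [str(gene_ids[i]) for i in key[:n]]


@dataclass(frozen=True)
class NbTestConfig:
    pseudocount: float = 0.5
    dispersion_shrinkage: float = 0.5  # weight of the trend in the shrunk dispersion
    min_cells_expressed: int = 3
    n_trend_bins: int = 20
    max_dispersion: float = 10.0


def nb_test(
    counts: np.ndarray,
    group1_mask: np.ndarray,
    factors: np.ndarray | None = None,
    cfg: NbTestConfig = NbTestConfig(),
) -> pd.DataFrame:
    """Per-gene NB Wald test of group 1 vs group 2.

    Returns a frame with base_mean, mean_g1, mean_g2, log2fc (group 1
    relative to group 2, pseudocount-stabilized), dispersion and the
    two-sided p.  Genes expressed in fewer than ``min_cells_expressed``
    cells (and all-zero genes) are untested: p is NaN.
    """
    counts = np.asarray(counts, dtype=float)
    group1_mask = np.asarray(group1_mask, dtype=bool)
    n1, n2 = int(group1_mask.sum()), int((~group1_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 cells")
    if factors is None:
        factors = size_factors(counts)
    y = counts / factors[None, :]
    y1, y2 = y[:, group1_mask], y[:, ~group1_mask]
    m1 = y1.mean(axis=1)
    m2 = y2.mean(axis=1)
    base_mean = y.mean(axis=1)

    # within-group pooled variance of normalized counts -> moment dispersion
    ss = ((y1 - m1[:, None]) ** 2).sum(axis=1) + ((y2 - m2[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / max(n1 + n2 - 2, 1)
    inv_s_mean = np.mean(1.0 / factors)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_raw = (pooled_var - base_mean * inv_s_mean) / base_mean**2
    disp_raw = np.clip(np.nan_to_num(disp_raw, nan=0.0), 1e-8, cfg.max_dispersion)

    # shrink toward a binned-median mean-dispersion trend
    expressed = (counts > 0).sum(axis=1) >= max(cfg.min_cells_expressed, 1)
    trend = np.full_like(disp_raw, np.median(disp_raw[expressed]) if expressed.any() else 1e-8)
    if expressed.sum() >= 10:
        order = np.flatnonzero(expressed)[np.argsort(base_mean[expressed], kind="stable")]
        for b in np.array_split(order, min(cfg.n_trend_bins, max(1, order.size // 10))):
            if b.size:
                trend[b] = np.median(disp_raw[b])
    w = cfg.dispersion_shrinkage
    disp = np.clip(w * trend + (1 - w) * disp_raw, 1e-8, cfg.max_dispersion)

    pc = cfg.pseudocount
    log2fc = np.log2((m1 + pc) / (m2 + pc))

    # delta-method SE of log group means: Var(y_c) = mu/s_c + alpha mu^2
    inv_s1 = np.sum(1.0 / factors[group1_mask])
    inv_s2 = np.sum(1.0 / factors[~group1_mask])
    var_mean1 = (m1 * inv_s1 + disp * m1**2 * n1) / n1**2
    var_mean2 = (m2 * inv_s2 + disp * m2**2 * n2) / n2**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se_log = np.sqrt(var_mean1 / (m1 + pc) ** 2 + var_mean2 / (m2 + pc) ** 2)
        z = np.log((m1 + pc) / (m2 + pc)) / se_log
    p = 2.0 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)
    p = np.where(expressed & (se_log > 0), p, np.nan)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "mean_g1": m1,
            "mean_g2": m2,
            "log2fc": log2fc,
            "dispersion": disp,
            "p_value": p,
        }
    )


def bh_fdr(p_values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate.

    Missing p-values are excluded from the number of tests m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values outside [0, 1]")
    from statsmodels.stats.multitest import multipletests

    out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def call_degs(
    results: pd.DataFrame,
    gene_ids: Sequence[str],
    alpha: float = 0.05,
    lfc_min: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label genes up/down/ns at the study thresholds and summarize.

    up: FDR < alpha and log2fc >= lfc_min (group 1 over group 2);
    down: FDR < alpha and log2fc <= -lfc_min; everything else ns.
    """
    out = results.copy()
    out.insert(0, "gene_id", list(gene_ids))
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    sig = out["fdr"] < alpha
    direction = np.where(
        sig & (out["log2fc"] >= lfc_min), "up",
        np.where(sig & (out["log2fc"] <= -lfc_min), "down", "ns"),
    )
    direction = np.where(np.isnan(out["fdr"]), "ns", direction)
    out["direction"] = direction
    n_up = int((out["direction"] == "up").sum())
    n_down = int((out["direction"] == "down").sum())
    return out, {"n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}


def pca_embed(
    counts: np.ndarray,
    gene_ids: Sequence[str],
    hvg: Sequence[str],
    n_components: int = 10,
    factors: np.ndarray | None = None,
) -> np.ndarray:
    """Cells x components PCA scores on log-normalized, scaled HVG data.

    Deterministic sign convention: each component is flipped so that its
    largest-|loading| gene coordinate is positive.
    """
    counts = np.asarray(counts, dtype=float)
    n_cells = counts.shape[1]
    if n_components > min(len(hvg), n_cells):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes={len(hvg)}, cells={n_cells})"
        )
    if factors is None:
        factors = size_factors(counts)
    idx = {g: i for i, g in enumerate(gene_ids)}
    rows = [idx[g] for g in hvg]
    X = np.log1p(counts[rows] / factors[None, :]).T  # cells x genes
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            scores[:, k] *= -1
    return scores
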