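"""Joint analysis of paired methylation and expression matrices.

Two components: (1) a joint non-negative matrix factorization that shares
one cell-loading matrix H across the expression and methylation layers
(multiplicative updates on ||X_rna - W_rna H||^2 + lambda ||X_meth -
W_meth H||^2), used to cluster cells and rank factor markers; (2)
within-group Pearson correlation between region methylation and gene
expression for cis (locus midpoint to TSS < 500 kb) pairs, retained when
the group's |r| >= 0.5, the between-group correlation difference exceeds
0.1, and the pair's best |r| clears a 0.2 guard.

The factorization imputes missing methylation entries with the region's
cross-cell mean (NMF needs complete non-negative input); the correlation
analysis instead uses pairwise-complete observations and never imputes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneRecord, GenomicRegion

_EPS = 1e-12


@dataclass
class FactorModel:
    H: np.ndarray  # factors x cells, non-negative cell loadings
    W_rna: np.ndarray  # genes x factors
    W_meth: np.ndarray  # loci x factors
    cell_ids: list[str]
    objective_trace: list[float]

    @property
    def n_factors(self) -> int:
        return self.H.shape[0]

    @property
    def factor_assignment(self) -> np.ndarray:
        """1-based factor of maximal loading per cell."""
        return np.argmax(self.H, axis=0) + 1


@dataclass(frozen=True)
class CorrelationConfig:
    max_distance: int = 500_000
    min_abs_r: float = 0.5
    min_r_diff: float = 0.1
    guard_r: float = 0.2
    min_pairs: int = 5
    apply_min_abs_r: bool = True
    apply_r_diff: bool = True
    apply_guard: bool = True


def impute_missing_mean(X: np.ndarray) -> np.ndarray:
    """Replace NaNs with the feature's cross-cell mean (0 if all missing)."""
    X = np.array(X, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(X, axis=1)
    row_mean = np.nan_to_num(row_mean, nan=0.0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.broadcast_to(row_mean[:, None], X.shape)[nan_mask]
    return X


def joint_nmf(
    X_rna: np.ndarray,
    X_meth: np.ndarray,
    cell_ids: Sequence[str],
    K: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    lam: float = 1.0,
) -> FactorModel:
    """Joint NMF with a shared cell-loading matrix H.

    Multiplicative updates guarantee a non-increasing objective; the run is
    deterministic given ``seed``.  With ``lam=0`` the factorization is fit
    on the expression layer alone and W_meth is fit post-hoc with H held
    fixed.
    """
    X_r = np.asarray(X_rna, dtype=float)
    X_m = np.asarray(X_meth, dtype=float)
    if np.isnan(X_m).any():
        X_m = impute_missing_mean(X_m)
    if np.any(X_r < 0) or np.any(X_m < 0):
        raise ValueError("inputs must be non-negative")
    n_cells = X_r.shape[1]
    if X_m.shape[1] != n_cells or len(cell_ids) != n_cells:
        missing = max(X_r.shape[1], X_m.shape[1], len(cell_ids)) - min(
            X_r.shape[1], X_m.shape[1], len(cell_ids)
        )
        raise ValueError(
            f"cell-set mismatch: rna={X_r.shape[1]}, meth={X_m.shape[1]}, "
            f"ids={len(cell_ids)} ({missing} cells differ)"
        )
    if K > n_cells:
        raise ValueError(f"K={K} exceeds {n_cells} cells")

    rng = np.random.default_rng(seed)
    scale = max(np.sqrt(X_r.mean() / K), _EPS)
    W_r = rng.uniform(0.1, 1.0, size=(X_r.shape[0], K)) * scale
    H = rng.uniform(0.1, 1.0, size=(K, n_cells)) * scale
    scale_m = max(np.sqrt(max(X_m.mean(), _EPS) / K), _EPS)
    W_m = rng.uniform(0.1, 1.0, size=(X_m.shape[0], K)) * scale_m

    def objective(W_r, W_m, H) -> float:
        loss = float(np.sum((X_r - W_r @ H) ** 2))
        if lam > 0:
            loss += lam * float(np.sum((X_m - W_m @ H) ** 2))
        return loss

    trace = [objective(W_r, W_m, H)]
    for _ in range(max_iter):
        HHt = H @ H.T
        W_r *= (X_r @ H.T) / (W_r @ HHt + _EPS)
        if lam > 0:
            W_m *= (X_m @ H.T) / (W_m @ HHt + _EPS)
        num = W_r.T @ X_r
        den = (W_r.T @ W_r) @ H
        if lam > 0:
            num = num + lam * (W_m.T @ X_m)
            den = den + lam * (W_m.T @ W_m) @ H
        H *= num / (den + _EPS)
        trace.append(objective(W_r, W_m, H))
        if abs(trace[-2] - trace[-1]) <= tol * max(trace[-2], _EPS):
            break
    if lam == 0:
        # W_meth fit post-hoc against the fixed H
        for _ in range(100):
            W_m *= (X_m @ H.T) / (W_m @ (H @ H.T) + _EPS)
    return FactorModel(H, W_r, W_m, list(cell_ids), trace)


def rank_factor_markers(
    model: FactorModel,
    X: np.ndarray,
    feature_ids: Sequence[str],
    alpha: float = 0.05,
    min_fc: float = 0.25,
) -> pd.DataFrame:
    """Per-factor marker features: assigned cells vs the rest.

    Wilcoxon rank-sum p plus a natural-log fold-change of group means;
    features with p < alpha and lfc > min_fc are retained, ranked by fold
    change within each factor.
    """
    X = np.asarray(X, dtype=float)
    assign = model.factor_assignment
    rows = []
    for k in range(1, model.n_factors + 1):
        in_k = assign == k
        if in_k.sum() < 2 or (~in_k).sum() < 2:
            warnings.warn(f"factor {k} has <2 assigned cells; markers undefined", stacklevel=2)
            continue
        mean_in = X[:, in_k].mean(axis=1)
        mean_out = X[:, ~in_k].mean(axis=1)
        eps = 1e-9
        lfc = np.log((mean_in + eps) / (mean_out + eps))
        for i, fid in enumerate(feature_ids):
            if np.all(X[i, in_k] == X[i, in_k][0]) and np.all(X[i, ~in_k] == X[i, in_k][0]):
                continue  # identical across cells: no marker
            p = float(stats.ranksums(X[i, in_k], X[i, ~in_k]).pvalue)
            if p < alpha and lfc[i] > min_fc:
                rows.append(
                    {"factor": k, "feature_id": str(fid), "p_value": p,
                     "log_fc": float(lfc[i])}
                )
    out = pd.DataFrame(rows, columns=["factor", "feature_id", "p_value", "log_fc"])
    if len(out):
        out = out.sort_values(["factor", "log_fc"], ascending=[True, False]).reset_index(drop=True)
        out["rank"] = out.groupby("factor").cumcount() + 1
    else:
        out["rank"] = pd.Series(dtype=int)
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_meth_expr(
    meth: pd.DataFrame,
    loci: Sequence[GenomicRegion],
    expr: pd.DataFrame,
    genes: Sequence[GeneRecord],
    groups: Mapping[str, str],
    cfg: CorrelationConfig = CorrelationConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-group methylation-expression correlation for cis pairs.

    ``meth`` is loci x cells (fractions, NaN = missing), ``expr`` genes x
    cells on the scale to correlate (log-normalized expression).  Candidate
    pairs are same-chromosome (locus, gene) pairs with |locus midpoint -
    TSS| < ``max_distance``.  For each group, Pearson r and p use
    pairwise-complete cells (>= ``min_pairs`` required in BOTH groups).  A
    pair is reported for group g iff |r_g| >= min_abs_r, |r_g - r_other| >
    min_r_diff, and max(|r_g|, |r_other|) > guard_r.  Returns the record
    table and per-group positive/negative sign counts.
    """
    cell_ids = list(meth.columns)
    if list(expr.columns) != cell_ids:
        raise ValueError("meth and expr must share an identical ordered cell set")
    labels = np.array([groups[c] for c in cell_ids])
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    locus_by_id = {r.region_id: r for r in loci}
    missing_loci = set(meth.index) - set(locus_by_id)
    if missing_loci:
        raise ValueError(f"loci without metadata: {sorted(missing_loci)[:5]} ...")

    # cis candidates per chromosome via sorted TSS arrays
    genes_by_chrom: dict[str, tuple[np.ndarray, list[GeneRecord]]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.tss)
        genes_by_chrom[chrom] = (np.array([g.tss - 1 for g in sub]), sub)
    expr_row = {g: i for i, g in enumerate(expr.index)}
    meth_values = meth.to_numpy()
    expr_values = expr.to_numpy()
    masks = {u: labels == u for u in uniq}

    rows = []
    for li, locus_id in enumerate(meth.index):
        region = locus_by_id[locus_id]
        if region.chrom not in genes_by_chrom:
            continue
        tss_arr, sub = genes_by_chrom[region.chrom]
        mid = region.midpoint
        lo = int(np.searchsorted(tss_arr, mid - cfg.max_distance, side="right"))
        hi = int(np.searchsorted(tss_arr, mid + cfg.max_distance, side="left"))
        for g in sub[lo:hi]:
            dist = abs(mid - (g.tss - 1))
            if dist >= cfg.max_distance or g.gene_id not in expr_row:
                continue
            gi = expr_row[g.gene_id]
            r_by, p_by, ok = {}, {}, True
            for u in uniq:
                m = masks[u]
                x = meth_values[li, m]
                y = expr_values[gi, m]
                complete = ~np.isnan(x) & ~np.isnan(y)
                if complete.sum() < cfg.min_pairs:
                    ok = False
                    break
                xs, ys = x[complete], y[complete]
                if np.all(xs == xs[0]) or np.all(ys == ys[0]):
                    ok = False  # zero-variance vector: pair skipped
                    break
                r_by[u], p_by[u] = _pearson(xs, ys)
            if not ok:
                continue
            for u in uniq:
                other = [v for v in uniq if v != u][0]
                r_g, r_o = r_by[u], r_by[other]
                if cfg.apply_guard and max(abs(r_g), abs(r_o)) <= cfg.guard_r:
                    continue
                if cfg.apply_min_abs_r and abs(r_g) < cfg.min_abs_r:
                    continue
                if cfg.apply_r_diff and abs(r_g - r_o) <= cfg.min_r_diff:
                    continue
                rows.append(
                    {
                        "locus_id": locus_id,
                        "gene_id": g.gene_id,
                        "group": u,
                        "r": r_g,
                        "p_value": p_by[u],
                        "r_other": r_o,
                        "distance_bp": float(dist),
                        "sign": "positive" if r_g > 0 else "negative",
                    }
                )
    records = pd.DataFrame(
        rows,
        columns=["locus_id", "gene_id", "group", "r", "p_value", "r_other",
                 "distance_bp", "sign"],
    )
    summary_rows = []
    for u in uniq:
        sub = records[records["group"] == u]
        summary_rows.append(
            {
                "group": u,
                "n_records": len(sub),
                "n_positive": int((sub["sign"] == "positive").sum()),
                "n_negative": int((sub["sign"] == "negative").sum()),
            }
        )
    return records, pd.DataFrame(summary_rows)
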