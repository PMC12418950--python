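import numpy as np
import pandas as pd
import pytest

from scmethrna.integration import (
    CorrelationConfig,
    correlate_meth_expr,
    impute_missing_mean,
    joint_nmf,
    rank_factor_markers,
)
from scmethrna.io_formats import GeneRecord, GenomicRegion
from scmethrna.synthetic_data import SimConfig, simulate_block_multiomics, simulate_coupled_omics


def exact_corr_vector(x, r, rng):
    """A vector with sample Pearson correlation exactly r against x."""
    z = rng.normal(size=x.size)
    x_c = (x - x.mean()) / x.std()
    z_c = z - z.mean() - np.dot(z - z.mean(), x_c) / np.dot(x_c, x_c) * x_c
    z_c /= z_c.std()
    return r * x_c + np.sqrt(1 - r**2) * z_c


class TestJointNmf:
    def setup_method(self):
        self.X_rna, self.X_meth, self.labels = simulate_block_multiomics(seed=0)
        self.cells = [f"c{i}" for i in range(self.X_rna.shape[1])]

    def test_block_structure_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        model = joint_nmf(self.X_rna, self.X_meth, self.cells, K=2, seed=0)
        assert adjusted_rand_score(self.labels, model.factor_assignment) == 1.0

    def test_objective_trace_non_increasing(self):
        model = joint_nmf(self.X_rna, self.X_meth, self.cells, K=3, seed=1)
        tr = np.array(model.objective_trace)
        assert np.all(np.diff(tr) <= 1e-8 * tr[:-1] + 1e-9)
        assert tr[-1] <= tr[0]

    def test_seed_reproducibility_and_stability(self):
        m1 = joint_nmf(self.X_rna, self.X_meth, self.cells, K=2, seed=5)
        m2 = joint_nmf(self.X_rna, self.X_meth, self.cells, K=2, seed=5)
        assert np.array_equal(m1.H, m2.H)
        from sklearn.metrics import adjusted_rand_score

        m3 = joint_nmf(self.X_rna, self.X_meth, self.cells, K=2, seed=99)
        # different seeds may permute factor labels but not the partition
        assert adjusted_rand_score(m1.factor_assignment, m3.factor_assignment) == 1.0

    def test_lambda_zero_decouples_methylation(self):
        other_meth = np.random.default_rng(0).uniform(0, 5, self.X_meth.shape)
        m1 = joint_nmf(self.X_rna, self.X_meth, self.cells, K=2, seed=3, lam=0.0)
        m2 = joint_nmf(self.X_rna, other_meth, self.cells, K=2, seed=3, lam=0.0)
        assert np.array_equal(m1.H, m2.H)
        assert np.array_equal(m1.W_rna, m2.W_rna)

    def test_cell_mismatch_raises(self):
        with pytest.raises(ValueError, match="cell-set mismatch"):
            joint_nmf(self.X_rna, self.X_meth[:, :-1], self.cells, K=2)

    def test_k_exceeds_cells_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            joint_nmf(self.X_rna[:, :3], self.X_meth[:, :3], self.cells[:3], K=4)

    def test_missing_methylation_imputed(self):
        X = self.X_meth.copy()
        X[0, :5] = np.nan
        model = joint_nmf(self.X_rna, X, self.cells, K=2, seed=0)
        assert np.isfinite(model.objective_trace[-1])


def test_impute_missing_mean_row_wise():
    X = np.array([[1.0, np.nan, 3.0], [np.nan, np.nan, np.nan]])
    out = impute_missing_mean(X)
    assert out[0].tolist() == [1.0, 2.0, 3.0]
    assert out[1].tolist() == [0.0, 0.0, 0.0]


class TestFactorMarkers:
    def _model(self, n_per=6):
        X_rna, X_meth, labels = simulate_block_multiomics(n_cells_per_group=n_per, seed=2)
        cells = [f"c{i}" for i in range(2 * n_per)]
        return joint_nmf(X_rna, X_meth, cells, K=2, seed=0), X_rna

    def test_factor_exclusive_feature_is_top_marker(self):
        model, X = self._model()
        X = X.copy()
        X[0] = 0.0
        X[0, model.factor_assignment == 1] = 9.0
        ids = [f"f{i}" for i in range(X.shape[0])]
        markers = rank_factor_markers(model, X, ids)
        f1 = markers[markers["factor"] == 1]
        assert f1.iloc[0]["feature_id"] == "f0"
        assert f1.iloc[0]["rank"] == 1

    def test_constant_feature_excluded(self):
        model, X = self._model()
        X = X.copy()
        X[1] = 3.14
        markers = rank_factor_markers(model, X, [f"f{i}" for i in range(X.shape[0])])
        assert "f1" not in set(markers["feature_id"])

    def test_trivial_thresholds_retain_everything_varying(self):
        model, X = self._model()
        ids = [f"f{i}" for i in range(X.shape[0])]
        markers = rank_factor_markers(model, X, ids, alpha=1.0, min_fc=-np.inf)
        assert set(markers["feature_id"]) == set(ids)


class TestCorrelateMethExpr:
    def _setup(self, n_cells=24):
        genes = [GeneRecord("gA", "chr1", "+", 10_001, 10_001, 12_000),
                 GeneRecord("gB", "chr2", "+", 10_001, 10_001, 12_000)]
        loci = [GenomicRegion("chr1", 8_000, 12_000, "promoter", "pA", gene_id="gA")]
        cells = [f"c{i}" for i in range(n_cells)]
        groups = {c: ("IVM" if i < n_cells // 2 else "invivo")
                  for i, c in enumerate(cells)}
        return genes, loci, cells, groups

    def test_exact_affine_anticorrelation_retained_negative(self):
        genes, loci, cells, groups = self._setup()
        rng = np.random.default_rng(0)
        expr_row = rng.normal(1, 0.5, len(cells))
        meth_row = 0.9 - 0.5 * (expr_row - expr_row.min()) / np.ptp(expr_row)
        # group 2 uncorrelated
        meth_row[12:] = rng.uniform(0.2, 0.8, 12)
        meth = pd.DataFrame([meth_row], index=["pA"], columns=cells)
        expr = pd.DataFrame([expr_row, rng.normal(size=len(cells))],
                            index=["gA", "gB"], columns=cells)
        records, summary = correlate_meth_expr(meth, loci, expr, genes, groups)
        ivm = records[records["group"] == "IVM"]
        assert len(ivm) == 1
        assert ivm.iloc[0]["r"] == pytest.approx(-1.0, abs=1e-9)
        assert ivm.iloc[0]["sign"] == "negative"

    def test_trans_chromosome_pair_never_candidate(self):
        genes, loci, cells, groups = self._setup()
        rng = np.random.default_rng(1)
        shared = rng.normal(size=len(cells))
        meth = pd.DataFrame([0.5 + 0.3 * np.tanh(shared)], index=["pA"], columns=cells)
        # gB perfectly coupled but on chr2: must not appear
        expr = pd.DataFrame([rng.normal(size=len(cells)), shared],
                            index=["gA", "gB"], columns=cells)
        records, _ = correlate_meth_expr(meth, loci, expr, genes, groups)
        assert "gB" not in set(records["gene_id"])

    def test_small_between_group_difference_rejected(self):
        genes, loci, cells, groups = self._setup()
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=12)
        x2 = rng.normal(size=12)
        expr_row = np.concatenate([x1, x2])
        meth_row = np.concatenate([
            0.5 + 0.2 * exact_corr_vector(x1, 0.60, rng),
            0.5 + 0.2 * exact_corr_vector(x2, 0.55, rng),
        ])
        meth = pd.DataFrame([meth_row], index=["pA"], columns=cells)
        expr = pd.DataFrame([expr_row, rng.normal(size=24)],
                            index=["gA", "gB"], columns=cells)
        records, _ = correlate_meth_expr(meth, loci, expr, genes, groups)
        assert len(records) == 0  # |0.60 - 0.55| = 0.05 <= 0.1

    def test_pearson_matches_brute_force(self):
        rng = np.random.default_rng(3)
        from scmethrna.integration import _pearson

        for _ in range(50):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, _ = _pearson(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            brute = np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
            assert r == pytest.approx(brute, abs=1e-12)

    def test_planted_negative_couplings_recovered(self):
        cfg = SimConfig(seed=0, n_cells_per_group=14, n_genes=200)
        data = simulate_coupled_omics(cfg, n_loci=150, n_pairs_planted=40)
        groups = dict(zip(data["groups"]["cell_id"], data["groups"]["group"]))
        records, _ = correlate_meth_expr(
            data["meth"], data["loci"], data["expr"], data["genes"], groups)
        planted = set(zip(data["truth_pairs"]["locus_id"], data["truth_pairs"]["gene_id"]))
        ivm = records[records["group"] == "IVM"].set_index(["locus_id", "gene_id"])
        recovered = {p for p in planted
                     if p in ivm.index and ivm.loc[p, "sign"] == "negative"}
        assert len(recovered) / len(planted) >= 0.9
        other = records[records["group"] != "IVM"]
        leaked = set(zip(other["locus_id"], other["gene_id"])) & planted
        assert len(planted - leaked) / len(planted) >= 0.9
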