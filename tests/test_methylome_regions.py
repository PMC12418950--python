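import numpy as np
import pandas as pd
import pytest

from scmethrna.io_formats import CpGCall, GeneRecord, GenomicRegion
from scmethrna.methylome_regions import (
    aggregate_region,
    detect_vmrs,
    gene_body_regions,
    imprint_report,
    promoter_regions,
    tile_windows,
)
from tests.conftest import make_region_matrix


def region(start, end, cls="CGI", rid=None, chrom="chr1"):
    return GenomicRegion(chrom, start, end, cls, rid or f"{cls}:{chrom}:{start}-{end}")


class TestAggregateRegion:
    def test_read_weighted_pooling(self):
        cells = {"c": [CpGCall("chr1", 10, 3, 1), CpGCall("chr1", 20, 2, 2)]}
        mat = aggregate_region(cells, [region(0, 100)], min_cov_per_cpg=1)
        assert mat.meth_fraction[0, 0] == pytest.approx(5 / 8)
        assert mat.n_cpgs_covered[0, 0] == 2
        assert mat.total_reads[0, 0] == 8

    def test_cpg_mean_pooling(self):
        cells = {"c": [CpGCall("chr1", 10, 3, 1), CpGCall("chr1", 20, 2, 2)]}
        mat = aggregate_region(cells, [region(0, 100)], min_cov_per_cpg=1,
                               pooling="cpg_mean")
        assert mat.meth_fraction[0, 0] == pytest.approx((0.75 + 0.5) / 2)

    def test_min_coverage_excludes_shallow_cpgs(self):
        cells = {"c": [CpGCall("chr1", 10, 3, 1), CpGCall("chr1", 20, 2, 2)]}
        mat = aggregate_region(cells, [region(0, 100)], min_cov_per_cpg=5)
        assert np.isnan(mat.meth_fraction[0, 0])
        assert mat.n_cpgs_covered[0, 0] == 0

    def test_region_without_cpgs_missing(self):
        cells = {"c": [CpGCall("chr1", 10, 3, 1)]}
        mat = aggregate_region(cells, [region(500, 600)], min_cov_per_cpg=1)
        assert np.isnan(mat.meth_fraction[0, 0])

    def test_position_convention_half_open(self):
        # 1-based pos p belongs to [p-1, p): pos 100 is in [99,100) not [100,...)
        cells = {"c": [CpGCall("chr1", 100, 1, 0)]}
        mat = aggregate_region(cells, [region(99, 100), region(100, 200)],
                               min_cov_per_cpg=1)
        assert mat.n_cpgs_covered[0, 0] == 1
        assert mat.n_cpgs_covered[1, 0] == 0

    def test_overlapping_regions_share_cpgs(self):
        cells = {"c": [CpGCall("chr1", 50, 4, 0)]}
        mat = aggregate_region(cells, [region(0, 100), region(40, 60)],
                               min_cov_per_cpg=1)
        assert mat.total_reads[:, 0].tolist() == [4, 4]

    def test_empty_region_set_raises(self):
        with pytest.raises(ValueError, match="empty region set"):
            aggregate_region({"c": []}, [], 1)

    def test_whole_chromosome_region_reproduces_global_methylation(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(1, 10_000), 300, replace=False))
        nm = rng.integers(0, 5, 300)
        nu = rng.integers(0, 5, 300)
        keep = nm + nu > 0
        frame = pd.DataFrame({"chrom": "chr1", "pos": pos[keep],
                              "n_meth": nm[keep], "n_unmeth": nu[keep]})
        mat = aggregate_region({"c": frame}, [region(0, 10_000)], min_cov_per_cpg=1)
        expected = frame["n_meth"].sum() / (frame["n_meth"].sum() + frame["n_unmeth"].sum())
        assert mat.meth_fraction[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_window_reads_conserve_chromosome_total(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(np.arange(1, 5_000), 200, replace=False))
        frame = pd.DataFrame({"chrom": "chr1", "pos": pos,
                              "n_meth": rng.integers(1, 5, 200),
                              "n_unmeth": rng.integers(0, 5, 200)})
        windows = tile_windows({"chr1": 5_000}, 250)
        mat = aggregate_region({"c": frame}, windows, min_cov_per_cpg=1)
        assert mat.total_reads.sum() == (frame["n_meth"] + frame["n_unmeth"]).sum()


class TestTileWindows:
    def test_short_last_window(self):
        w = tile_windows({"chr1": 2500}, 1000)
        assert [(r.start, r.end) for r in w] == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_exact_fit_single_window(self):
        w = tile_windows({"chr1": 1000}, 1000)
        assert [(r.start, r.end) for r in w] == [(0, 1000)]

    def test_width_larger_than_chromosome(self):
        w = tile_windows({"chr1": 700}, 10**9)
        assert [(r.start, r.end) for r in w] == [(0, 700)]

    def test_nonpositive_width_raises(self):
        with pytest.raises(ValueError, match="width"):
            tile_windows({"chr1": 100}, 0)


class TestDetectVmrs:
    def test_constant_window_never_selected(self):
        frac = np.vstack([np.full(10, 0.5), np.linspace(0, 1, 10)])
        mat = make_region_matrix(frac)
        calls = detect_vmrs(mat, top_fraction=0.5)
        ids = {c.region.region_id for c in calls}
        assert "VMR:chr1:1000-2000" in ids and "VMR:chr1:0-1000" not in ids

    def test_bimodal_window_variance_closed_form(self):
        n = 10
        bimodal = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
        frac = np.vstack([bimodal, np.full(n, 0.5) + np.linspace(-0.01, 0.01, n)])
        mat = make_region_matrix(frac)
        calls = detect_vmrs(mat, top_fraction=0.5)
        top = min(calls, key=lambda c: c.rank)
        assert top.region.start == 0
        assert top.variance_across_cells == pytest.approx(0.25 * n / (n - 1))

    def test_adjacent_selected_windows_merge(self):
        rng = np.random.default_rng(0)
        frac = np.vstack([
            rng.choice([0.0, 1.0], 12),          # window (0,1000), high var
            rng.choice([0.0, 1.0], 12),          # window (1000,2000), high var
            np.full(12, 0.5),
            np.full(12, 0.5),
        ])
        mat = make_region_matrix(frac)
        calls = detect_vmrs(mat, top_fraction=0.5)
        assert len(calls) == 1
        assert (calls[0].region.start, calls[0].region.end) == (0, 2000)
        assert calls[0].n_windows == 2

    def test_undercovered_windows_ineligible(self):
        frac = np.vstack([
            [0.0, 1.0, np.nan, np.nan, np.nan, np.nan],  # 2 of 6 cells only
            [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        ])
        mat = make_region_matrix(frac)
        calls = detect_vmrs(mat, top_fraction=1.0)
        assert {c.region.region_id for c in calls} == {"VMR:chr1:1000-2000"}

    def test_no_eligible_windows_warns_empty(self):
        mat = make_region_matrix(np.full((2, 6), np.nan))
        with pytest.warns(UserWarning, match="no eligible"):
            assert detect_vmrs(mat) == []

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(7)
        frac = rng.uniform(0, 1, size=(30, 12))
        mat = make_region_matrix(frac)
        perm = rng.permutation(12)
        mat_perm = make_region_matrix(frac[:, perm],
                                      cell_ids=[f"cell_{i}" for i in perm])
        a = [(c.region.region_id, c.rank) for c in detect_vmrs(mat, 0.1)]
        b = [(c.region.region_id, c.rank) for c in detect_vmrs(mat_perm, 0.1)]
        assert a == b

    def test_recovers_planted_high_variance_windows(self):
        rng = np.random.default_rng(5)
        n_w, n_c, n_planted = 200, 16, 10
        frac = np.clip(rng.normal(0.5, 0.03, size=(n_w, n_c)), 0, 1)
        planted = rng.choice(n_w, n_planted, replace=False)
        for w in planted:
            frac[w] = rng.choice([0.02, 0.98], n_c)
        mat = make_region_matrix(frac)
        calls = detect_vmrs(mat, top_fraction=n_planted / n_w)
        starts = set()
        for c in calls:
            starts.update(range(c.region.start // 1000, c.region.end // 1000))
        recall = len(starts & set(planted.tolist())) / n_planted
        assert recall >= 0.9


class TestAnnotationHelpers:
    def test_promoter_window_is_strand_symmetric(self):
        plus = GeneRecord("g+", "chr1", "+", 10_001, 10_001, 12_000)
        minus = GeneRecord("g-", "chr1", "-", 10_001, 8_500, 10_001)
        for g in (plus, minus):
            (p,) = promoter_regions([g])
            assert (p.start, p.end) == (8_000, 12_000)

    def test_gene_body_coordinates(self):
        g = GeneRecord("g", "chr1", "+", 101, 101, 500)
        (b,) = gene_body_regions([g])
        assert (b.start, b.end) == (100, 500)


class TestImprintReport:
    def test_stable_region_appropriate(self):
        frac = np.array([[0.93, 0.93, 0.93, 0.93]])
        mat = make_region_matrix(frac, feature_class="imprinted_gDMR")
        groups = {"cell_0": "IVM", "cell_1": "IVM", "cell_2": "invivo", "cell_3": "invivo"}
        rep = imprint_report(mat, groups, tolerance=0.1)
        assert bool(rep.iloc[0]["appropriate"])

    def test_shifted_region_flagged(self):
        frac = np.array([[0.9, 0.9, 0.4, 0.4]])
        mat = make_region_matrix(frac, feature_class="imprinted_gDMR")
        groups = {"cell_0": "IVM", "cell_1": "IVM", "cell_2": "invivo", "cell_3": "invivo"}
        rep = imprint_report(mat, groups, tolerance=0.1)
        assert not bool(rep.iloc[0]["appropriate"])
        assert rep.iloc[0]["difference"] == pytest.approx(0.5)

    def test_empty_region_set_empty_table(self):
        mat = make_region_matrix(np.zeros((0, 4)))
        groups = {f"cell_{i}": ("IVM" if i < 2 else "invivo") for i in range(4)}
        assert len(imprint_report(mat, groups)) == 0
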