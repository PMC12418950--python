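import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmethrna.dm_caller import (
    DmFilterConfig,
    call_dmrs,
    dm_filter_cascade,
    dm_test,
    hypo_fraction_percent,
    results_to_frame,
    summarize_dmrs,
)
from tests.conftest import make_region_matrix


def pooled_t_reference(x, y):
    """Textbook pooled-variance two-sample t, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), n1 + n2 - 2)


def welch_t_reference(x, y):
    """Textbook Welch t with Welch-Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), df)


class TestDmTest:
    def test_identical_groups(self):
        t, p = dm_test([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert (t, p) == (0.0, 1.0)

    def test_student_matches_textbook_value(self):
        # g1=(0.1,0.2,0.3), g2=(0.6,0.7,0.8): sp=0.1, t = -0.5/(0.1*sqrt(2/3))
        t, p = dm_test([0.1, 0.2, 0.3], [0.6, 0.7, 0.8], variant="student")
        expected_t = -0.5 / (0.1 * math.sqrt(2 / 3))
        assert t == pytest.approx(expected_t, abs=1e-10)
        ref_t, ref_p = pooled_t_reference([0.1, 0.2, 0.3], [0.6, 0.7, 0.8])
        assert p == pytest.approx(ref_p, abs=1e-12)

    def test_welch_equals_student_for_equal_variances_and_sizes(self):
        x, y = [0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8]
        assert dm_test(x, y, "welch") == pytest.approx(dm_test(x, y, "student"))

    def test_single_value_group_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            dm_test([0.5], [0.1, 0.2])

    def test_degenerate_unequal_constant_groups(self):
        t, p = dm_test([0.0, 0.0], [1.0, 1.0])
        assert t == -math.inf and p == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_textbook_formulas_on_random_input(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        n1 = data.draw(st.integers(2, 12))
        n2 = data.draw(st.integers(2, 12))
        x = rng.uniform(0, 1, n1)
        y = rng.uniform(0, 1, n2)
        ts, ps = dm_test(x, y, "student")
        rt, rp = pooled_t_reference(x, y)
        assert ts == pytest.approx(rt, abs=1e-10)
        assert ps == pytest.approx(rp, abs=1e-10)
        tw, pw = dm_test(x, y, "welch")
        rtw, rpw = welch_t_reference(x, y)
        assert tw == pytest.approx(rtw, abs=1e-10)
        assert pw == pytest.approx(rpw, abs=1e-10)


class TestFilterCascade:
    def _groups(self, n=4):
        return {f"cell_{i}": ("IVM" if i < n else "invivo") for i in range(2 * n)}

    def test_boundary_region_retained(self):
        # 4+4 cells, covered in exactly 2 of 4 per group (ceil(0.5*4)=2),
        # mean region reads 12 per group
        frac = np.array([[0.5, 0.4, np.nan, np.nan, 0.6, 0.2, np.nan, np.nan]])
        reads = np.array([[12, 12, 0, 0, 12, 12, 0, 0]])
        mat = make_region_matrix(frac, reads=reads)
        retained, drops = dm_filter_cascade(mat, self._groups())
        assert retained.tolist() == [0]
        assert drops == {"rule2": 0, "rule3": 0}

    def test_rule2_half_of_cells_per_group(self):
        frac = np.array([[0.5, 0.4, 0.3, 0.2, 0.6, np.nan, np.nan, np.nan]])
        mat = make_region_matrix(frac)
        retained, drops = dm_filter_cascade(mat, self._groups())
        assert retained.size == 0
        assert drops["rule2"] == 1

    def test_rule3_strictly_greater_than_ten(self):
        frac = np.array([[0.5, 0.4, 0.3, 0.2, 0.6, 0.5, 0.4, 0.3]])
        reads = np.array([[10, 10, 10, 10, 20, 20, 20, 20]])  # g1 mean exactly 10
        mat = make_region_matrix(frac, reads=reads)
        retained, drops = dm_filter_cascade(mat, self._groups())
        assert retained.size == 0
        assert drops == {"rule2": 0, "rule3": 1}

    def test_not_two_groups_raises(self):
        mat = make_region_matrix(np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError, match="two groups"):
            dm_filter_cascade(mat, {"cell_0": "a", "cell_1": "a"})

    def test_matches_brute_force_enumeration(self):
        """Retained set equals a rule-by-rule brute-force evaluation."""
        rng = np.random.default_rng(42)
        n_regions, n_cells = 6, 8
        groups = self._groups()
        cfg = DmFilterConfig()
        for trial in range(25):
            frac = rng.uniform(0, 1, size=(n_regions, n_cells))
            frac[rng.random(frac.shape) < 0.4] = np.nan
            reads = rng.integers(1, 30, size=(n_regions, n_cells))
            reads[np.isnan(frac)] = 0
            ncpg = (reads > 0).astype(int)
            mat = make_region_matrix(frac, ncpg=ncpg, reads=reads)
            retained, _ = dm_filter_cascade(mat, groups, cfg)
            expected = []
            for r in range(n_regions):
                ok = True
                for mask in (slice(0, 4), slice(4, 8)):
                    vals = frac[r, mask]
                    covered = ~np.isnan(vals)
                    if covered.sum() < math.ceil(0.5 * 4):
                        ok = False
                        break
                    if reads[r, mask][covered].mean() <= 10:
                        ok = False
                        break
                if ok:
                    expected.append(r)
            assert retained.tolist() == expected

    def test_tightening_thresholds_is_monotone(self):
        rng = np.random.default_rng(9)
        frac = rng.uniform(0, 1, size=(40, 8))
        frac[rng.random(frac.shape) < 0.3] = np.nan
        reads = rng.integers(1, 40, size=(40, 8))
        reads[np.isnan(frac)] = 0
        mat = make_region_matrix(frac, ncpg=(reads > 0).astype(int), reads=reads)
        groups = self._groups()
        base, _ = dm_filter_cascade(mat, groups, DmFilterConfig())
        for cfg in (DmFilterConfig(min_cell_fraction_per_group=0.75),
                    DmFilterConfig(min_mean_reads_per_group=20)):
            tighter, _ = dm_filter_cascade(mat, groups, cfg)
            assert set(tighter.tolist()) <= set(base.tolist())


class TestCallDmrs:
    def _matrix_and_groups(self, mean1, mean2, n=4, spread=0.02):
        offsets = np.linspace(-spread, spread, n)
        frac = np.array([np.concatenate([mean1 + offsets, mean2 + offsets])])
        groups = {f"cell_{i}": ("IVM" if i < n else "invivo") for i in range(2 * n)}
        return make_region_matrix(frac), groups

    def test_significant_hyper_vs_intermediate(self):
        mat, groups = self._matrix_and_groups(0.80, 0.30)
        (r,) = call_dmrs(mat, groups)
        assert r.significant
        assert (r.level_label_g1, r.level_label_g2) == ("hyper", "intermediate")

    def test_small_delta_not_significant_despite_p(self):
        mat, groups = self._matrix_and_groups(0.50, 0.45, spread=0.005)
        (r,) = call_dmrs(mat, groups)
        assert r.p_value < 0.05 and not r.significant

    def test_hypo_label_in_group1(self):
        mat, groups = self._matrix_and_groups(0.20, 0.60)
        (r,) = call_dmrs(mat, groups)
        assert r.significant and r.level_label_g1 == "hypo"

    def test_labels_never_contradictory(self):
        rng = np.random.default_rng(13)
        frac = rng.uniform(0, 1, size=(50, 8))
        groups = {f"cell_{i}": ("IVM" if i < 4 else "invivo") for i in range(8)}
        results = call_dmrs(make_region_matrix(frac), groups)
        for r in results:
            assert r.level_label_g1 in {"hyper", "hypo", "intermediate"}
            assert r.level_label_g2 in {"hyper", "hypo", "intermediate"}

    def test_untested_region_reported_not_dropped(self):
        frac = np.array([[0.5, np.nan, np.nan, np.nan, 0.4, 0.5, 0.6, 0.5]])
        groups = {f"cell_{i}": ("IVM" if i < 4 else "invivo") for i in range(8)}
        results = call_dmrs(make_region_matrix(frac), groups,
                            DmFilterConfig(min_cell_fraction_per_group=0.25,
                                           min_mean_reads_per_group=1),
                            cascade_applied=True)
        assert len(results) == 1
        assert results[0].status.startswith("untested")
        assert not results[0].significant


class TestSummarize:
    def test_hypo_percentages_from_printed_counts(self):
        assert hypo_fraction_percent(42, 52) == 81
        assert hypo_fraction_percent(13, 15) == 87

    def test_empty_results_all_zero(self):
        table = summarize_dmrs([])
        assert len(table) == 0

    def test_summary_counts(self):
        mat, groups = TestCallDmrs()._matrix_and_groups(0.20, 0.80)
        results = call_dmrs(mat, groups)
        table = summarize_dmrs(results)
        row = table.iloc[0]
        assert row["n_significant"] == 1
        assert row["n_hypo_g1"] == 1 and row["n_hyper_g2"] == 1
        assert row["pct_hypo_g1"] == 100 and row["pct_hypo_g2"] == 0
        frame = results_to_frame(results)
        assert frame.iloc[0]["significant"]
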