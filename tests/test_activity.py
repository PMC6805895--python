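import numpy as np
import pandas as pd
import pytest
from scipy import stats

import immunemap as im
from immunemap import (
    CellGroups,
    compare_groups,
    module_score,
    pathway_heatmap_matrix,
    polarization_scores,
    score_all,
    select_variant_genes,
    significance_code,
    staining_table,
)

from conftest import make_matrix, truth_groups


def groups_of(labels, cells):
    return CellGroups(tuple(cells), np.asarray(labels, dtype=object))


def matrix_with_variances(variances, names=None):
    """Two-cell matrix whose gene rows have exactly the given sample variances."""
    names = names or [f"g{i + 1}" for i in range(len(variances))]
    rows = [[np.sqrt(v / 2.0), -np.sqrt(v / 2.0)] for v in variances]
    return make_matrix(rows, genes=names)


@pytest.mark.parametrize(
    "p, code",
    [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.07, "·"), (0.5, ""),
     (0.001, "**"), (0.05, "·"), (float("nan"), "")],
)
def test_significance_code_mapping(p, code):
    assert significance_code(p) == code


class TestSelectVariantGenes:
    def test_top_half_kept(self):
        m = matrix_with_variances([4, 3, 2, 1])
        assert select_variant_genes(m, ["g1", "g2", "g3", "g4"]) == ["g1", "g2"]

    def test_single_gene_kept(self):
        m = matrix_with_variances([1.0])
        assert select_variant_genes(m, ["g1"]) == ["g1"]

    def test_odd_count_with_ties(self):
        m = matrix_with_variances([5, 5, 5, 1, 1], names=["e", "b", "d", "a", "c"])
        # ceil(5/2)=3: the three variance-5 genes, lexicographic on ties
        assert select_variant_genes(m, ["a", "b", "c", "d", "e"]) == ["b", "d", "e"]

    def test_absent_genes_dropped_first(self):
        m = matrix_with_variances([4, 1])
        assert select_variant_genes(m, ["g1", "g2", "missing"]) == ["g1"]

    def test_empty_intersection_rejected(self):
        m = matrix_with_variances([1.0])
        with pytest.raises(ValueError, match="no genes"):
            select_variant_genes(m, ["nope"])


class TestModuleScore:
    def test_cell_score_is_mean(self):
        m = make_matrix([[1.0, 5.0], [3.0, 7.0]])
        scores, _ = module_score(m, ["g1", "g2"])
        assert scores["c1"] == 2.0 and scores["c2"] == 6.0

    def test_centered_matrix_has_zero_grand_score(self, default_dataset):
        _, _, matrix, _ = default_dataset
        genes = list(matrix.genes[:10])
        _, grand = module_score(matrix, genes)
        assert grand == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_fixture(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        scores, grand = module_score(m, ["g1", "g2", "g3"])
        np.testing.assert_allclose(scores.to_numpy(), [3.0, 4.0])
        assert grand == 3.5


class TestCompareGroups:
    def test_identical_scores_give_null_result(self):
        m = make_matrix([[1.0, 2.0, 1.0, 2.0]])
        g = groups_of(["group1", "group1", "group2", "group2"], m.cells)
        row = compare_groups(m, ["g1"], g)
        assert row.t == 0.0 and row.p == 1.0 and row.code == "" and row.direction == ""

    def test_welch_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2, 9)
        m = make_matrix(np.concatenate([a, b])[None, :])
        g = groups_of(["group1"] * 12 + ["group2"] * 9, m.cells)
        row = compare_groups(m, ["g1"], g)
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        se2 = v1 / 12 + v2 / 9
        t_ref = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((v1 / 12) ** 2 / 11 + (v2 / 9) ** 2 / 8)
        p_ref = 2 * stats.t.sf(abs(t_ref), df)
        assert row.t == pytest.approx(t_ref, abs=1e-12)
        assert row.p == pytest.approx(p_ref, abs=1e-12)

    def test_group_swap_antisymmetry(self, ranked_dataset):
        hierarchy, matrix, _, _, groups = ranked_dataset
        gene_set = hierarchy.genes("module", hierarchy.names("module")[0])
        row = compare_groups(matrix, gene_set, groups)
        swapped = compare_groups(matrix, gene_set, groups.swapped())
        assert swapped.t == pytest.approx(-row.t, rel=1e-12)
        assert swapped.p == pytest.approx(row.p, rel=1e-12)
        assert swapped.code == row.code

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(4, 20))
        m = make_matrix(values)
        g = groups_of(["group1"] * 10 + ["group2"] * 10, m.cells)
        row = compare_groups(m, list(m.genes), g)
        selected = select_variant_genes(m, list(m.genes))
        shifted = values.copy()
        shifted[m.gene_positions(selected)] += 3.7
        row_shift = compare_groups(make_matrix(shifted), list(m.genes), g)
        assert row_shift.t == pytest.approx(row.t, rel=1e-12)
        assert row_shift.mean_group1 == pytest.approx(row.mean_group1 + 3.7, rel=1e-12)

    def test_small_group_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        g = groups_of(["group1", "group2", "group2"], m.cells)
        with pytest.raises(ValueError, match="at least 2 cells"):
            compare_groups(m, ["g1"], g)

    def test_planted_active_module_strongly_significant(self, default_dataset):
        hierarchy, _, matrix, truth = default_dataset
        groups = truth_groups(matrix, truth)
        active = sorted(truth.active_modules)[0]
        row = compare_groups(matrix, hierarchy.genes("module", active), groups)
        assert row.p < 0.001 and row.code == "***"

    def test_planted_inactive_module_not_flagged(self, default_dataset):
        hierarchy, _, matrix, truth = default_dataset
        groups = truth_groups(matrix, truth)
        inactive = sorted(set(hierarchy.names("module")) - truth.active_modules)[0]
        row = compare_groups(matrix, hierarchy.genes("module", inactive), groups)
        assert row.p > 0.001


class TestScoreAll:
    def test_zone_level_has_two_rows(self, ranked_dataset):
        hierarchy, matrix, _, _, groups = ranked_dataset
        table = score_all(matrix, hierarchy, groups, level="zone")
        assert list(table["name"]) == list(hierarchy.names("zone"))

    def test_matches_per_module_calls(self, ranked_dataset):
        hierarchy, matrix, _, _, groups = ranked_dataset
        table = score_all(matrix, hierarchy, groups, level="module").set_index("name")
        for name in list(hierarchy.names("module"))[:3]:
            row = compare_groups(matrix, hierarchy.genes("module", name), groups)
            assert table.loc[name, "t"] == pytest.approx(row.t)

    def test_unmeasured_set_flagged_skipped(self):
        h = im.build_hierarchy(
            {"Z": ["MM"]}, {"MM": ["m1", "m2"]},
            {"m1": ["p1"], "m2": ["p2"]},
            {"p1": ["g1"], "p2": ["far"]},
        )
        m = make_matrix([[1.0, 2.0, 0.5, 1.5]], genes=["g1"])
        g = groups_of(["group1", "group1", "group2", "group2"], m.cells)
        table = score_all(m, h, g, level="module").set_index("name")
        assert not table.loc["m1", "skipped"]
        assert table.loc["m2", "skipped"] and np.isnan(table.loc["m2", "t"])

    def test_flagged_modules_are_the_planted_ones(self, default_dataset):
        hierarchy, _, matrix, truth = default_dataset
        groups = truth_groups(matrix, truth)
        table = score_all(matrix, hierarchy, groups, level="module")
        flagged = set(table.loc[table["p"] < 0.05, "name"])
        assert truth.active_modules <= flagged
        assert len(flagged - truth.active_modules) <= 1


class TestPolarization:
    def test_group1_is_anti_tumor_side(self, ranked_dataset):
        hierarchy, matrix, _, _, groups = ranked_dataset
        table = polarization_scores(matrix, hierarchy, groups).set_index("name")
        anti = table.loc[im.ANTI_TUMOR_ZONE]
        assert anti["direction"] == "group1" and anti["p"] < 0.01

    def test_swap_negates_t(self, ranked_dataset):
        hierarchy, matrix, _, _, groups = ranked_dataset
        t1 = polarization_scores(matrix, hierarchy, groups)["t"].to_numpy()
        t2 = polarization_scores(matrix, hierarchy, groups.swapped())["t"].to_numpy()
        np.testing.assert_allclose(t1, -t2, rtol=1e-12)

    def test_requires_two_zones(self, ranked_dataset):
        _, matrix, _, _, groups = ranked_dataset
        h = im.build_hierarchy(
            {"Z": ["MM"]}, {"MM": ["m"]}, {"m": ["p"]}, {"p": ["g1"]}
        )
        with pytest.raises(ValueError, match="2 zones"):
            polarization_scores(matrix, h, groups)


class TestStaining:
    def test_colors_follow_means(self):
        table = pd.DataFrame(
            [
                {"name": "s1", "level": "module", "mean_group1": 0.4,
                 "mean_group2": -0.1, "t": 2.0, "p": 0.01, "code": "*",
                 "direction": "group1", "n_genes": 3, "skipped": False},
            ]
        )
        st = staining_table(table).set_index("group")
        assert st.loc["group1", "color"] == "red"
        assert st.loc["group2", "color"] == "green"

    def test_tie_is_neutral(self):
        table = pd.DataFrame(
            [
                {"name": "s1", "level": "zone", "mean_group1": 0.2,
                 "mean_group2": 0.2, "t": 0.0, "p": 1.0, "code": "",
                 "direction": "", "n_genes": 2, "skipped": False},
            ]
        )
        assert (staining_table(table)["color"] == "").all()

    def test_csv_round_trip(self, tmp_path, ranked_dataset):
        hierarchy, matrix, _, _, groups = ranked_dataset
        st = staining_table(polarization_scores(matrix, hierarchy, groups))
        path = tmp_path / "stain.csv"
        st.to_csv(path, index=False)
        back = pd.read_csv(path, keep_default_na=False)
        pd.testing.assert_frame_equal(back, st, check_dtype=False)


class TestPathwayHeatmap:
    def _hierarchy_with_sizes(self, sizes):
        pathways = {
            f"p{i}": [f"g{i}_{j}" for j in range(size)] for i, size in enumerate(sizes)
        }
        return im.build_hierarchy(
            {"Z": ["MM"]}, {"MM": ["m"]}, {"m": list(pathways)}, pathways
        )

    def test_more_than_ten_molecules_rule(self):
        h = self._hierarchy_with_sizes([10, 11])
        genes = [g for p in h.pathways.values() for g in p]
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(len(genes), 12)), genes=genes)
        g = groups_of(["group1"] * 6 + ["group2"] * 6, m.cells)
        scores, codes = pathway_heatmap_matrix(m, h, g)
        assert list(scores.index) == ["p1"]  # the 11-gene pathway only

    def test_included_count_matches_direct_count(self, ranked_dataset):
        hierarchy, matrix, _, _, groups = ranked_dataset
        scores, codes = pathway_heatmap_matrix(matrix, hierarchy, groups, min_genes=11)
        direct = sum(
            len(matrix.present_genes(hierarchy.genes("pathway", p))) >= 11
            for p in hierarchy.names("pathway")
        )
        assert len(scores) == direct == len(codes)
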