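import numpy as np
import pytest
from scipy.stats import spearmanr

import immunemap as im
from immunemap import (
    CellGroups,
    ComponentResult,
    orient_component,
    pca_coordinates,
    run_ica,
    split_by_quartiles,
    split_by_sign,
)

from conftest import make_matrix


def manual_result(projections, loadings, genes, cells):
    projections = np.asarray(projections, dtype=float).reshape(len(cells), -1)
    loadings = np.asarray(loadings, dtype=float).reshape(len(genes), -1)
    return ComponentResult(
        projections=projections,
        loadings=loadings,
        stability=np.ones(projections.shape[1]),
        genes=tuple(genes),
        cells=tuple(cells),
    )


class TestRunICA:
    def test_recovers_planted_gradient(self, default_dataset):
        hierarchy, _, matrix, truth = default_dataset
        result = run_ica(matrix, seed=0)
        rho = abs(spearmanr(result.ic1_projection(), truth.latent).statistic)
        assert rho >= 0.8
        assert result.stability[0] >= 0.7
        assert (np.diff(result.stability) <= 1e-12).all()  # sorted non-increasing

    def test_identical_run_seeds_give_unit_stability(self, default_dataset):
        _, _, matrix, _ = default_dataset
        result = run_ica(matrix, n_components=1, n_runs=4, run_seeds=[7, 7, 7, 7])
        assert result.stability[0] == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_noise_has_no_stable_component(self):
        below = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            matrix = im.preprocess(
                make_matrix(rng.normal(size=(300, 100))).to_frame()
            )
            result = run_ica(matrix, seed=seed + 500)
            below += result.stability[0] < im.ranking.DEFAULT_STABILITY_THRESHOLD
        assert below >= 8

    def test_top_components_decorrelated(self, default_dataset):
        _, _, matrix, _ = default_dataset
        result = run_ica(matrix, seed=1)
        r = np.corrcoef(result.projections[:, 0], result.projections[:, 1])[0, 1]
        assert abs(r) <= 0.1

    def test_uncentered_matrix_rejected(self):
        with pytest.raises(ValueError, match="centred"):
            run_ica(make_matrix(np.ones((5, 5))))

    def test_agrees_with_external_fastica(self, default_dataset):
        # independent route: sklearn's FastICA on the same data should find a
        # component essentially identical to IC1
        sklearn_decomposition = pytest.importorskip("sklearn.decomposition")
        _, _, matrix, _ = default_dataset
        ours = run_ica(matrix, seed=2).ic1_projection()
        ica = sklearn_decomposition.FastICA(
            n_components=10, random_state=0, max_iter=500, whiten="unit-variance"
        )
        sources = ica.fit_transform(matrix.values.T)  # cells × k
        best = max(
            abs(np.corrcoef(sources[:, j], ours)[0, 1]) for j in range(sources.shape[1])
        )
        assert best >= 0.9


class TestOrientation:
    def test_negative_zone_loading_flipped(self, chain_hierarchy):
        res = manual_result([1.0, -2.0], [-0.3, -0.3], ["g1", "g2"], ["c1", "c2"])
        oriented = orient_component(res, chain_hierarchy)
        np.testing.assert_allclose(oriented.ic1_loading(), [0.3, 0.3])
        np.testing.assert_allclose(oriented.ic1_projection(), [-1.0, 2.0])

    def test_zero_mean_loading_unchanged(self, chain_hierarchy):
        res = manual_result([1.0, -2.0], [0.3, -0.3], ["g1", "g2"], ["c1", "c2"])
        oriented = orient_component(res, chain_hierarchy)
        np.testing.assert_allclose(oriented.ic1_loading(), [0.3, -0.3])

    def test_idempotent(self, chain_hierarchy):
        res = manual_result([1.0, -2.0], [-0.3, -0.3], ["g1", "g2"], ["c1", "c2"])
        once = orient_component(res, chain_hierarchy)
        twice = orient_component(once, chain_hierarchy)
        np.testing.assert_array_equal(once.projections, twice.projections)

    def test_disjoint_gene_sets_rejected(self, chain_hierarchy):
        res = manual_result([1.0], [0.5], ["other"], ["c1"])
        with pytest.raises(ValueError, match="no gene of zone"):
            orient_component(res, chain_hierarchy)

    def test_sign_invariance_of_groups(self, default_dataset):
        # ICA's component sign is arbitrary: negating IC1 (projections and
        # loadings together) must yield identical groups after orientation
        import dataclasses

        hierarchy, _, matrix, _ = default_dataset
        result = run_ica(matrix, seed=3)
        negated = dataclasses.replace(
            result, projections=-result.projections, loadings=-result.loadings
        )
        g_orig = split_by_sign(orient_component(result, hierarchy))
        g_neg = split_by_sign(orient_component(negated, hierarchy))
        assert (g_orig.labels == np.asarray(g_neg.labels)).all()


class TestSplits:
    def test_sign_split(self):
        res = manual_result([1, 2, -1, -3], [1.0], ["g1"], ["c1", "c2", "c3", "c4"])
        groups = split_by_sign(res)
        assert groups.members("group1") == ("c1", "c2")
        assert groups.members("group2") == ("c3", "c4")

    def test_zero_projection_unassigned(self):
        res = manual_result([1, 0, -1], [1.0], ["g1"], ["c1", "c2", "c3"])
        assert split_by_sign(res).members("unassigned") == ("c2",)

    def test_one_sided_projections_rejected(self):
        res = manual_result([1, 2, 3], [1.0], ["g1"], ["c1", "c2", "c3"])
        with pytest.raises(ValueError, match="empty"):
            split_by_sign(res)

    def test_quartile_split_of_1_to_8(self):
        cells = [f"c{i}" for i in range(1, 9)]
        res = manual_result(np.arange(1.0, 9.0), [1.0], ["g1"], cells)
        groups = split_by_quartiles(res)
        assert groups.members("group2") == ("c1", "c2")
        assert groups.members("group1") == ("c7", "c8")
        assert len(groups.members("unassigned")) == 4

    def test_degenerate_ties_rejected(self):
        cells = [f"c{i}" for i in range(8)]
        res = manual_result(np.ones(8), [1.0], ["g1"], cells)
        with pytest.raises(ValueError, match="ties"):
            split_by_quartiles(res)

    def test_too_few_cells_rejected(self):
        res = manual_result([1, 2, 3], [1.0], ["g1"], ["c1", "c2", "c3"])
        with pytest.raises(ValueError, match="8 cells"):
            split_by_quartiles(res)

    def test_swapped_groups(self):
        res = manual_result([1, 0, -1], [1.0], ["g1"], ["c1", "c2", "c3"])
        swapped = split_by_sign(res).swapped()
        assert swapped.members("group2") == ("c1",)
        assert swapped.members("unassigned") == ("c2",)

    def test_quartile_extremes_pure_on_synthetic_data(self, ranked_dataset):
        _, _, truth, result, _ = ranked_dataset
        groups = split_by_quartiles(result)
        labels = np.asarray(groups.labels)
        planted = np.where(truth.groups == 1, "group1", "group2")
        chosen = labels != "unassigned"
        purity = (labels[chosen] == planted[chosen]).mean()
        assert purity >= 0.95 or purity <= 0.05  # up to global swap


class TestPCA:
    def test_rank_one_matrix_has_single_component(self):
        t = np.linspace(-1, 1, 6)
        values = np.outer([1.0, 2.0, -1.0], t)
        matrix = im.preprocess(make_matrix(values).to_frame())
        coords = pca_coordinates(matrix, k=2)
        assert coords[:, 1].var() == pytest.approx(0.0, abs=1e-16)

    def test_projected_variance_bounded(self, default_dataset):
        _, _, matrix, _ = default_dataset
        coords = pca_coordinates(matrix, k=2)
        total = matrix.values.var(ddof=0) * matrix.n_genes
        assert coords.var(axis=0, ddof=0).sum() <= total * (1 + 1e-12)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(10, 6))
        matrix = im.preprocess(make_matrix(values).to_frame())
        coords = pca_coordinates(matrix, k=3)
        x = matrix.values.T  # cells × genes
        cov = x.T @ x / x.shape[0]  # gene covariance
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:3]
        oracle = x @ evecs[:, order]
        for j in range(3):
            sign = np.sign(oracle[:, j] @ coords[:, j])
            np.testing.assert_allclose(coords[:, j], sign * oracle[:, j], atol=1e-8)

    def test_k_too_large_rejected(self):
        matrix = im.preprocess(make_matrix(np.ones((3, 4))).to_frame())
        with pytest.raises(ValueError, match="exceeds"):
            pca_coordinates(matrix, k=5)
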