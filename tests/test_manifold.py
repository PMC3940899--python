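"""Distances, neighbourhood graph, geodesics, classical MDS, and the pipeline."""

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from pwisomap import (
    CovarianceModel,
    DisconnectedGraphError,
    GeneExpressionMatrix,
    PathwayCollection,
    RunConfig,
    SingularCovarianceError,
    ValidationError,
    apriori_isomap,
    classical_mds,
    estimate_covariance,
    geodesic_distances,
    knn_graph,
    mahalanobis,
    plain_isomap,
    project_samples,
    weighted_distance_matrix,
)
from pwisomap.prior import JaccardMatrix, weight_matrix


class TestCovariance:
    def test_uncorrelated_unit_variance_gives_identity(self):
        rng = np.random.default_rng(0)
        X = GeneExpressionMatrix(
            rng.standard_normal((10000, 2)),
            [f"G{i}" for i in range(10000)],
            ["S1", "S2"],
        )
        cov = estimate_covariance(X, regularization=0.0)
        np.testing.assert_allclose(cov.matrix, np.eye(2), atol=0.05)
        np.testing.assert_allclose(cov.inverse, np.eye(2), atol=0.06)

    def test_rank_deficient_without_ridge_raises(self):
        X = GeneExpressionMatrix(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]],
            ["G1", "G2", "G3"],
            ["S1", "S2", "S3"],
        )
        with pytest.raises(SingularCovarianceError, match="regularization"):
            estimate_covariance(X, regularization=0.0)

    def test_ridge_on_zero_matrix_inverts_to_scaled_identity(self):
        X = GeneExpressionMatrix(
            np.ones((4, 3)), [f"G{i}" for i in range(4)], ["S1", "S2", "S3"]
        )
        cov = estimate_covariance(X, regularization=0.5)
        np.testing.assert_allclose(cov.inverse, np.eye(3) / 0.5, atol=1e-12)

    def test_inverse_times_matrix_is_identity(self, tiny_matrix):
        cov = estimate_covariance(tiny_matrix, regularization=1e-3)
        np.testing.assert_allclose(
            cov.inverse @ cov.matrix, np.eye(cov.matrix.shape[0]), atol=1e-8
        )


class TestMahalanobis:
    def test_identity_covariance_reduces_to_euclidean(self):
        cov = CovarianceModel.from_matrix(np.eye(2))
        assert mahalanobis([0, 0], [3, 4], cov) == pytest.approx(5.0)

    def test_zero_for_equal_points(self):
        cov = CovarianceModel.from_matrix(np.eye(3))
        assert mahalanobis([1, 2, 3], [1, 2, 3], cov) == 0.0

    def test_diagonal_covariance_rescales_axes(self):
        cov = CovarianceModel.from_matrix(np.diag([4.0, 1.0]))
        assert mahalanobis([2, 0], [0, 0], cov) == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        cov = CovarianceModel.from_matrix(np.eye(2))
        with pytest.raises(ValidationError):
            mahalanobis([1, 2, 3], [1, 2], cov)


class TestWeightedDistances:
    def test_neutral_weights_leave_base_untouched(self, tiny_matrix):
        cov = estimate_covariance(tiny_matrix, 1e-2)
        J = JaccardMatrix(np.zeros((20, 20)), tiny_matrix.gene_ids)
        W = weight_matrix(J, 5.0)  # exp(0) = 1 everywhere
        model = weighted_distance_matrix(tiny_matrix, W, cov)
        np.testing.assert_array_equal(model.weighted_distances, model.base_distances)

    def test_single_pair_halved_by_weight_two(self):
        X = GeneExpressionMatrix(
            [[0.0, 0.0], [3.0, 4.0]], ["G1", "G2"], ["S1", "S2"]
        )
        cov = CovarianceModel.from_matrix(np.eye(2))
        J = JaccardMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), ["G1", "G2"])
        W = weight_matrix(J, np.log(2.0))
        model = weighted_distance_matrix(X, W, cov)
        assert model.base_distances[0, 1] == pytest.approx(5.0)
        assert model.weighted_distances[0, 1] == pytest.approx(2.5)

    def test_matches_double_loop_brute_force(self, tiny_matrix):
        rng = np.random.default_rng(9)
        cov = estimate_covariance(tiny_matrix, 1e-2)
        Jv = rng.uniform(0, 1, size=(20, 20))
        Jv = (Jv + Jv.T) / 2
        np.fill_diagonal(Jv, 1.0)
        W = weight_matrix(JaccardMatrix(Jv, tiny_matrix.gene_ids), 2.0)
        model = weighted_distance_matrix(tiny_matrix, W, cov)
        for i in range(20):
            for j in range(20):
                expected = (
                    0.0
                    if i == j
                    else mahalanobis(
                        tiny_matrix.values[i], tiny_matrix.values[j], cov
                    )
                    / W.values[i, j]
                )
                assert model.weighted_distances[i, j] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_weighted_never_exceeds_base(self, tiny_matrix):
        cov = estimate_covariance(tiny_matrix, 1e-2)
        rng = np.random.default_rng(4)
        Jv = rng.uniform(0, 1, size=(20, 20))
        Jv = (Jv + Jv.T) / 2
        W = weight_matrix(JaccardMatrix(Jv, tiny_matrix.gene_ids), 3.0)
        model = weighted_distance_matrix(tiny_matrix, W, cov)
        assert np.all(model.weighted_distances <= model.base_distances + 1e-15)
        assert np.all(np.diag(model.weighted_distances) == 0)


class TestKnnGraph:
    def test_collinear_points_hand_checked(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [3.0]])))
        g = knn_graph(D, k=1)
        assert [(i, j) for i, j, _ in g.edges] == [(0, 1), (1, 2)]

    def test_k_equals_n_minus_one_gives_complete_graph(self):
        rng = np.random.default_rng(1)
        D = squareform(pdist(rng.normal(size=(6, 2))))
        g = knn_graph(D, k=5)
        assert len(g.edges) == 15

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(2)
        D = squareform(pdist(rng.normal(size=(30, 3))))
        k = 4
        g = knn_graph(D, k)
        expected = set()
        for i in range(30):
            order = sorted(range(30), key=lambda j: (D[i, j], j))
            nearest = [j for j in order if j != i][:k]
            expected |= {tuple(sorted((i, j))) for j in nearest}
        assert {(i, j) for i, j, _ in g.edges} == expected

    def test_k_out_of_range_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValidationError):
            knn_graph(D, 0)
        with pytest.raises(ValidationError):
            knn_graph(D, 3)


class TestGeodesics:
    def test_path_graph_accumulates_lengths(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [2.0]])))
        g = knn_graph(D, 1)
        DG = geodesic_distances(g)
        assert DG[0, 2] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_dijkstra_equals_floyd_warshall_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 50)
        D = squareform(pdist(rng.normal(size=(n, 4))))
        g = knn_graph(D, 4)
        dij = geodesic_distances(g, "dijkstra")
        fw = geodesic_distances(g, "floyd_warshall")
        np.testing.assert_allclose(dij, fw, rtol=1e-9)
        # independent oracle on the same edge set
        G = nx.Graph()
        G.add_nodes_from(range(n))
        G.add_weighted_edges_from(g.edges)
        ref = dict(nx.all_pairs_dijkstra_path_length(G))
        for i in range(n):
            for j in range(n):
                assert dij[i, j] == pytest.approx(ref[i][j], rel=1e-9)

    def test_metric_complete_graph_is_its_own_geodesic(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))  # Euclidean: triangle inequality holds
        g = knn_graph(D, 9)
        DG = geodesic_distances(g)
        np.testing.assert_allclose(DG, D, atol=1e-12)

    def test_geodesic_at_least_direct_distance(self, aligned_dataset, small_config):
        emb = plain_isomap(aligned_dataset.expression, small_config, "euclidean")
        direct = squareform(pdist(aligned_dataset.expression.values))
        assert np.all(emb.geodesic >= direct - 1e-9)

    def test_disconnected_graph_reports_component_sizes(self):
        # two far-apart pairs with k=1 stay disconnected
        D = squareform(pdist(np.array([[0.0], [1.0], [100.0], [101.0]])))
        g = knn_graph(D, 1)
        with pytest.raises(DisconnectedGraphError) as err:
            geodesic_distances(g)
        assert err.value.component_sizes == [2, 2]


class TestClassicalMds:
    def test_collinear_points_embed_on_a_line(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [2.0]])))
        emb = classical_mds(D, 1)
        tol = 1e-9 * max(abs(emb.eigenvalues[0]), 1.0)
        assert int(np.sum(emb.eigenvalues > tol)) == 1
        coords = emb.coordinates[:, 0]
        for i in range(3):
            for j in range(3):
                assert abs(coords[i] - coords[j]) == pytest.approx(D[i, j], abs=1e-10)

    def test_gram_rows_and_columns_sum_to_zero(self, tiny_matrix):
        D = squareform(pdist(tiny_matrix.values))
        emb = classical_mds(D, 2)
        bound = 1e-10 * D.shape[0] * np.abs(emb.gram).max()
        assert np.abs(emb.gram.sum(axis=0)).max() < bound
        assert np.abs(emb.gram.sum(axis=1)).max() < bound

    @pytest.mark.parametrize("seed", range(3))
    def test_flat_plane_in_high_dimension_is_isometric(self, seed):
        rng = np.random.default_rng(seed)
        plane = rng.normal(size=(30, 2))
        basis, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        points = plane @ basis.T  # 2-D plane embedded in 10-D
        D = squareform(pdist(points))
        emb = classical_mds(D, 2)
        np.testing.assert_allclose(
            squareform(pdist(emb.coordinates)), D, atol=1e-8
        )

    def test_too_many_components_reports_usable_count(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [2.0]])))
        with pytest.raises(ValidationError, match="1"):
            classical_mds(D, 2)

    def test_sign_convention_pins_largest_entry_positive(self, tiny_matrix):
        D = squareform(pdist(tiny_matrix.values))
        emb = classical_mds(D, 3)
        for i in range(3):
            pivot = np.argmax(np.abs(emb.coordinates[:, i]))
            assert emb.coordinates[pivot, i] > 0


class TestPipeline:
    def test_empty_pathways_collapse_to_plain_isomap(self, aligned_dataset, small_config):
        emb_a = apriori_isomap(
            aligned_dataset.expression, PathwayCollection({}), small_config
        )
        emb_p = plain_isomap(aligned_dataset.expression, small_config, "mahalanobis")
        np.testing.assert_array_equal(emb_a.coordinates, emb_p.coordinates)

    def test_sigma_zero_collapses_regardless_of_pathways(
        self, aligned_dataset
    ):
        cfg = RunConfig(k_neighbors=10, sigma=0.0, n_components_max=10)
        emb_a = apriori_isomap(
            aligned_dataset.expression, aligned_dataset.pathways, cfg
        )
        emb_p = plain_isomap(aligned_dataset.expression, cfg, "mahalanobis")
        np.testing.assert_array_equal(emb_a.coordinates, emb_p.coordinates)

    def test_euclidean_equals_mahalanobis_under_identity_covariance(self):
        rng = np.random.default_rng(8)
        # whiten exactly so the estimated covariance is the identity
        raw = rng.standard_normal((60, 4))
        raw = raw - raw.mean(axis=0)
        S = np.cov(raw, rowvar=False)
        L = np.linalg.cholesky(np.linalg.inv(S))
        X = GeneExpressionMatrix(
            raw @ L, [f"G{i}" for i in range(60)], [f"S{j}" for j in range(4)]
        )
        cfg = RunConfig(
            k_neighbors=6, n_components_max=3, covariance_regularization=0.0
        )
        emb_e = plain_isomap(X, cfg, "euclidean")
        emb_m = plain_isomap(X, cfg, "mahalanobis")
        np.testing.assert_allclose(
            emb_e.coordinates, emb_m.coordinates, atol=1e-6
        )

    def test_reference_isomap_agreement_on_swiss_roll(self):
        from scipy.stats import pearsonr
        from sklearn.datasets import make_swiss_roll
        from sklearn.manifold import Isomap

        pts, _ = make_swiss_roll(n_samples=200, random_state=0)
        X = GeneExpressionMatrix(
            pts, [f"G{i}" for i in range(200)], ["x", "y", "z"]
        )
        cfg = RunConfig(k_neighbors=10, n_components_max=2)
        emb = plain_isomap(X, cfg, "euclidean")
        ref = Isomap(n_neighbors=10, n_components=2).fit_transform(pts)
        r, _ = pearsonr(pdist(emb.coordinates), pdist(ref))
        assert r >= 0.99

    def test_largest_component_fallback_drops_small_component(self):
        positions = np.array([0, 1, 2, 3, 4, 5, 6, 7, 1000, 1000.5])
        vals = np.column_stack([positions, np.zeros(10)])
        X = GeneExpressionMatrix(
            vals, [f"G{i}" for i in range(10)], ["S1", "S2"]
        )
        cfg = RunConfig(k_neighbors=1, n_components_max=2, largest_component=True)
        emb = plain_isomap(X, cfg, "euclidean")
        assert np.isnan(emb.coordinates[-2:]).all()
        assert np.isfinite(emb.coordinates[:8]).all()

    def test_config_size_constraints_enforced(self, tiny_matrix):
        with pytest.raises(ValidationError, match="n_components_max"):
            plain_isomap(
                tiny_matrix, RunConfig(k_neighbors=3, n_components_max=50), "euclidean"
            )


class TestProjectSamples:
    def test_identity_matrix_returns_gene_basis(self):
        cfg = RunConfig(k_neighbors=2, n_components_max=2)
        X = GeneExpressionMatrix(np.eye(3), ["G1", "G2", "G3"], ["S1", "S2", "S3"])
        emb = plain_isomap(X, cfg, "euclidean")
        one = emb.coordinates[:, :1]
        projected = project_samples(emb, X)
        np.testing.assert_allclose(projected[:, :1], one, atol=1e-12)

    def test_linearity_in_expression(self, aligned_dataset, small_config):
        emb = plain_isomap(aligned_dataset.expression, small_config, "euclidean")
        base = project_samples(emb, aligned_dataset.expression)
        doubled = GeneExpressionMatrix(
            2.0 * aligned_dataset.expression.values,
            aligned_dataset.expression.gene_ids,
            aligned_dataset.expression.sample_ids,
        )
        np.testing.assert_allclose(
            project_samples(emb, doubled), 2.0 * base, rtol=1e-12
        )

    def test_projected_classes_beat_chance(self, aligned_dataset, small_config):
        from pwisomap import cross_validate

        emb = apriori_isomap(
            aligned_dataset.expression, aligned_dataset.pathways, small_config
        )
        coords = project_samples(emb, aligned_dataset.expression)[:, :2]
        mean_acc, _ = cross_validate(coords, aligned_dataset.labels, "knn", 5, 0)
        assert mean_acc > 0.7

    def test_shape_mismatch_rejected(self, aligned_dataset, small_config, tiny_matrix):
        emb = plain_isomap(aligned_dataset.expression, small_config, "euclidean")
        with pytest.raises(ValidationError):
            project_samples(emb, tiny_matrix)
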