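"""Weighted-metric Isomap in gene space and the sample-space projection.

Pipeline: regularized Mahalanobis distances between gene expression profiles,
optionally divided by the pathway-prior weights, a symmetrized k-nearest-
neighbour graph, all-pairs shortest paths (Dijkstra or Floyd-Warshall), and a
classical-MDS eigen-embedding of the geodesic matrix. Samples are projected
onto the gene-space manifold by multiplying the data matrix into the scaled
eigenbasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

from .datatypes import GeneExpressionMatrix, PathwayCollection, RunConfig
from .errors import DisconnectedGraphError, SingularCovarianceError, ValidationError
from .prior import WeightMatrix, jaccard_matrix, pathway_sets_per_gene, weight_matrix

# dense eigensolver below this node count, iterative (ARPACK) above
_DENSE_EIG_LIMIT = 2000


@dataclass
class CovarianceModel:
    """A (regularized) covariance matrix and its inverse for Mahalanobis distances."""

    matrix: np.ndarray
    inverse: np.ndarray
    regularization: float

    @classmethod
    def from_matrix(cls, S: np.ndarray, regularization: float = 0.0) -> "CovarianceModel":
        S = np.asarray(S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValidationError("covariance matrix must be square")
        if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
            raise ValidationError("covariance matrix must be symmetric")
        if regularization < 0:
            raise ValidationError("regularization must be non-negative")
        S_reg = S + regularization * np.eye(S.shape[0])
        try:
            chol = scipy.linalg.cho_factor(S_reg)
        except scipy.linalg.LinAlgError:
            raise SingularCovarianceError(
                "covariance matrix is singular; pass a positive regularization "
                "(ridge added to the diagonal) to make it invertible"
            ) from None
        inverse = scipy.linalg.cho_solve(chol, np.eye(S.shape[0]))
        inverse = (inverse + inverse.T) / 2.0
        return cls(S_reg, inverse, float(regularization))


def estimate_covariance(
    X: GeneExpressionMatrix, regularization: float | None = None
) -> CovarianceModel:
    """Sample covariance of the sample-space coordinates, estimated over genes.

    Gene expression profiles live in R^{n_samples}; the covariance of those
    coordinates is estimated treating each gene as one observation. With few
    genes (or any constant coordinate) the matrix is singular, so a ridge term
    is added to the diagonal before inversion; ``None`` selects the default
    1e-3 * mean(diagonal).
    """
    if X.n_samples < 2:
        raise ValidationError("covariance needs at least 2 samples")
    S = np.cov(X.values, rowvar=False)
    S = np.atleast_2d(S)
    if regularization is None:
        mean_diag = float(np.mean(np.diag(S)))
        regularization = 1e-3 * mean_diag if mean_diag > 0 else 1e-3
    return CovarianceModel.from_matrix(S, regularization)


def mahalanobis(x, y, cov: CovarianceModel) -> float:
    """Mahalanobis distance sqrt((x-y)^T S^-1 (x-y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"vectors must share one dimension, got {x.shape} vs {y.shape}")
    if x.shape[0] != cov.inverse.shape[0]:
        raise ValidationError(
            f"vectors of length {x.shape[0]} vs covariance of size {cov.inverse.shape[0]}"
        )
    d = x - y
    val = float(d @ cov.inverse @ d)
    return float(np.sqrt(max(val, 0.0)))


@dataclass
class WeightedDistanceModel:
    """Base Mahalanobis distances, the prior weights, and their quotient."""

    base_distances: np.ndarray
    weights: WeightMatrix
    weighted_distances: np.ndarray


def mahalanobis_distance_matrix(X: GeneExpressionMatrix, cov: CovarianceModel) -> np.ndarray:
    """All-pairs Mahalanobis distances between gene profiles (rows of X)."""
    D = squareform(pdist(X.values, metric="mahalanobis", VI=cov.inverse))
    np.fill_diagonal(D, 0.0)
    return D


def weighted_distance_matrix(
    X: GeneExpressionMatrix, W: WeightMatrix, cov: CovarianceModel
) -> WeightedDistanceModel:
    """Divide the gene-to-gene Mahalanobis distances by the prior weights.

    Weights are >= 1, so genes sharing pathways can only get closer; a neutral
    (all-ones) weight matrix leaves the base metric untouched.
    """
    if list(W.gene_ids) != list(X.gene_ids):
        raise ValidationError("weight matrix gene order does not match expression matrix")
    base = mahalanobis_distance_matrix(X, cov)
    weighted = base / W.values
    np.fill_diagonal(weighted, 0.0)
    return WeightedDistanceModel(base, W, weighted)


@dataclass
class NeighborhoodGraph:
    """Union-symmetrized kNN graph with edge lengths from the chosen metric."""

    adjacency: sp.csr_matrix  # symmetric; explicit entries are edge lengths
    k: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))


def knn_graph(D: np.ndarray, k: int) -> NeighborhoodGraph:
    """Connect each node to its k nearest distinct nodes; symmetrize by union.

    Ties in distance are broken by lower node index so the graph is a pure
    function of (D, k).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValidationError("distance matrix must be square")
    if not (1 <= k < n):
        raise ValidationError(f"k must satisfy 1 <= k < n_nodes; got k={k}, n={n}")
    rows, cols = [], []
    idx = np.arange(n)
    for i in range(n):
        # stable order: primary key distance, secondary key node index
        order = np.lexsort((idx, D[i]))
        order = order[order != i][:k]
        rows.extend([i] * len(order))
        cols.extend(order.tolist())
    mask = sp.coo_matrix((np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n))
    mask = ((mask + mask.T) > 0).tocoo()  # union symmetrization
    lengths = D[mask.row, mask.col]
    # duplicate points give zero-length edges; keep them explicit (tiny length)
    # so the sparse graph routines do not drop them
    lengths = np.where(lengths == 0.0, np.finfo(float).tiny, lengths)
    adjacency = sp.coo_matrix((lengths, (mask.row, mask.col)), shape=(n, n)).tocsr()
    return NeighborhoodGraph(adjacency, k)


def geodesic_distances(G: NeighborhoodGraph, algorithm: str = "dijkstra") -> np.ndarray:
    """All-pairs shortest-path lengths over the neighbourhood graph.

    Dijkstra and Floyd-Warshall agree to floating tolerance; Dijkstra is the
    default since the edge lengths are non-negative.
    """
    if algorithm not in ("dijkstra", "floyd_warshall"):
        raise ValidationError(f"unknown shortest-path algorithm {algorithm!r}")
    n_comp, labels = connected_components(G.adjacency, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise DisconnectedGraphError(sizes)
    method = "D" if algorithm == "dijkstra" else "FW"
    D = shortest_path(G.adjacency, method=method, directed=False)
    return (D + D.T) / 2.0


@dataclass
class GeodesicEmbedding:
    """Classical-MDS embedding of a geodesic distance matrix.

    coordinates[:, i] = sqrt(lambda_i) * v_i over the n_components largest
    positive eigenvalues of the double-centered Gram matrix.
    """

    geodesic: np.ndarray
    gram: np.ndarray
    eigenvalues: np.ndarray  # full available spectrum, sorted descending
    eigenvectors: np.ndarray  # columns aligned with eigenvalues
    coordinates: np.ndarray
    n_components: int
    node_ids: list[str] = field(default_factory=list)


def classical_mds(D_G: np.ndarray, n_components: int) -> GeodesicEmbedding:
    """Embed a distance matrix by eigendecomposition of B = -1/2 H D^2 H.

    Only positive eigenvalues are usable (geodesic matrices are generally
    non-Euclidean, so negative eigenvalues occur and are discarded).
    Eigenvector signs are fixed so each component's largest-magnitude entry is
    positive, which makes repeated runs bit-identical.
    """
    D_G = np.asarray(D_G, dtype=float)
    n = D_G.shape[0]
    if D_G.ndim != 2 or D_G.shape[1] != n:
        raise ValidationError("geodesic matrix must be square")
    if not np.allclose(np.diag(D_G), 0.0, atol=1e-12):
        raise ValidationError("geodesic matrix must have zero diagonal")
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    H = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * H @ (D_G**2) @ H
    B = (B + B.T) / 2.0
    if n <= _DENSE_EIG_LIMIT:
        eigvals, eigvecs = scipy.linalg.eigh(B)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    else:
        k = min(n - 1, n_components + 10)  # requested components + buffer
        eigvals, eigvecs = sp.linalg.eigsh(B, k=k, which="LA")
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(abs(eigvals[0]), 1.0)
    n_positive = int(np.sum(eigvals > tol))
    if n_components > n_positive:
        raise ValidationError(
            f"requested {n_components} components but only {n_positive} "
            "positive eigenvalues are available"
        )
    vecs = eigvecs[:, :n_components].copy()
    for i in range(n_components):
        pivot = np.argmax(np.abs(vecs[:, i]))
        if vecs[pivot, i] < 0:
            vecs[:, i] = -vecs[:, i]
    coords = vecs * np.sqrt(eigvals[:n_components])
    return GeodesicEmbedding(
        geodesic=D_G,
        gram=B,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        coordinates=coords,
        n_components=n_components,
    )


def _embed_distance_matrix(
    D: np.ndarray, config: RunConfig, node_ids: list[str]
) -> GeodesicEmbedding:
    """kNN graph -> geodesics -> classical MDS, honoring the config.

    If the graph is disconnected and ``config.largest_component`` is set, the
    embedding is restricted to the largest component (coordinates of dropped
    nodes are NaN); otherwise disconnection is a hard error.
    """
    graph = knn_graph(D, config.k_neighbors)
    keep = np.arange(D.shape[0])
    try:
        D_G = geodesic_distances(graph, config.shortest_path_algorithm)
    except DisconnectedGraphError:
        if not config.largest_component:
            raise
        _, labels = connected_components(graph.adjacency, directed=False)
        largest = np.argmax(np.bincount(labels))
        keep = np.flatnonzero(labels == largest)
        sub = D[np.ix_(keep, keep)]
        graph = knn_graph(sub, min(config.k_neighbors, len(keep) - 1))
        D_G = geodesic_distances(graph, config.shortest_path_algorithm)
    n_kept = len(keep)
    # cap components at what the spectrum can provide, never above the config
    probe = classical_mds(D_G, 1)
    tol = 1e-9 * max(abs(probe.eigenvalues[0]), 1.0)
    n_positive = int(np.sum(probe.eigenvalues > tol))
    n_components = min(config.n_components_max, n_positive, n_kept - 1)
    emb = classical_mds(D_G, n_components)
    if n_kept != D.shape[0]:
        full = np.full((D.shape[0], emb.coordinates.shape[1]), np.nan)
        full[keep] = emb.coordinates
        emb = GeodesicEmbedding(
            geodesic=emb.geodesic,
            gram=emb.gram,
            eigenvalues=emb.eigenvalues,
            eigenvectors=emb.eigenvectors,
            coordinates=full,
            n_components=emb.n_components,
        )
    emb.node_ids = list(node_ids)
    return emb


def apriori_isomap(
    X: GeneExpressionMatrix, pathways: PathwayCollection | None, config: RunConfig
) -> GeodesicEmbedding:
    """Pathway-weighted Isomap over genes.

    Composition: Jaccard co-membership -> exponential weights -> weighted
    Mahalanobis distances -> kNN graph -> geodesics -> classical MDS. With an
    empty pathway collection or sigma = 0 this is exactly plain Isomap under
    the Mahalanobis metric.
    """
    config.validate_for(X.n_genes)
    if pathways is None:
        pathways = PathwayCollection({})
    gene_pathways = pathway_sets_per_gene(pathways, X.gene_ids)
    J = jaccard_matrix(gene_pathways)
    W = weight_matrix(J, config.sigma)
    cov = estimate_covariance(X, config.covariance_regularization)
    model = weighted_distance_matrix(X, W, cov)
    return _embed_distance_matrix(model.weighted_distances, config, X.gene_ids)


def plain_isomap(
    X: GeneExpressionMatrix, config: RunConfig, metric: str = "euclidean"
) -> GeodesicEmbedding:
    """Unweighted Isomap over genes, with a Euclidean or Mahalanobis base metric."""
    config.validate_for(X.n_genes)
    if metric == "euclidean":
        D = squareform(pdist(X.values, metric="euclidean"))
    elif metric == "mahalanobis":
        cov = estimate_covariance(X, config.covariance_regularization)
        D = mahalanobis_distance_matrix(X, cov)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    return _embed_distance_matrix(D, config, X.gene_ids)


def project_samples(E: GeodesicEmbedding, X: GeneExpressionMatrix) -> np.ndarray:
    """Project samples onto the gene-space manifold: X^T times the scaled basis.

    The gene-space coordinates (sqrt(lambda)-scaled eigenvectors) act as the
    basis; each sample's coordinate along component i is the expression-
    weighted sum of the gene coordinates. Linear in X by construction.
    """
    coords = E.coordinates
    if coords.shape[0] != X.n_genes:
        raise ValidationError(
            f"embedding has {coords.shape[0]} genes but matrix has {X.n_genes}"
        )
    if np.isnan(coords).any():
        raise ValidationError(
            "embedding contains dropped (NaN) genes; restrict X to the "
            "embedded component before projecting"
        )
    return X.values.T @ coords
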