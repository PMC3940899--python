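"""Cluster validity and classification evaluation of embeddings.

Dunn Index with a centroid-linkage numerator, stratified k-fold CV accuracy
curves over component counts, trapezoidal aggregation of the curve, ROC/AUC
with kNN / linear SVM / LDA, and the Dunn-maximizing sigma sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datatypes import GeneExpressionMatrix, LabelVector, PathwayCollection, RunConfig
from .errors import ValidationError
from .manifold import (
    _embed_distance_matrix,
    estimate_covariance,
    mahalanobis_distance_matrix,
    project_samples,
)
from .prior import jaccard_matrix, pathway_sets_per_gene, weight_matrix

#: guard against a zero intra-cluster spread (singleton/duplicate clusters)
DUNN_EPSILON = 1e-12


@dataclass
class EvaluationReport:
    """Evaluation curves and summaries for one embedding."""

    dunn_by_components: dict[int, float]
    accuracy_by_components: dict[int, tuple[float, float]]  # (mean, variance)
    aggregate_accuracy: float
    auc: dict[str, float]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dunn_by_components": {str(k): v for k, v in self.dunn_by_components.items()},
            "accuracy_by_components": {
                str(k): {"mean": m, "variance": v}
                for k, (m, v) in self.accuracy_by_components.items()
            },
            "aggregate_accuracy": self.aggregate_accuracy,
            "auc": dict(self.auc),
            "config": dict(self.config),
        }


def dunn_index(
    coordinates: np.ndarray,
    labels: LabelVector,
    between: str = "centroid",
    epsilon: float = DUNN_EPSILON,
) -> float:
    """Ratio of minimal between-cluster separation to maximal within-cluster spread.

    The numerator is the minimum over cluster pairs of the centroid-to-centroid
    distance (or single-linkage with ``between="single"``); the denominator is
    the maximum over clusters of the mean distance of members to their
    centroid. Labels act as the cluster assignment. Higher is denser /
    better separated. When every cluster has zero spread the denominator is
    replaced by ``epsilon`` (degenerate but defined).
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim == 1:
        coordinates = coordinates[:, None]
    if not isinstance(labels, LabelVector):
        labels = LabelVector(labels)
    labels.check_alignment(coordinates.shape[0])
    labels.require_multiclass()
    if between not in ("centroid", "single"):
        raise ValidationError(f"unknown between-cluster linkage {between!r}")
    groups = {c: coordinates[labels.labels == c] for c in labels.classes}
    centroids = {c: g.mean(axis=0) for c, g in groups.items()}
    spreads = [
        float(np.linalg.norm(g - centroids[c], axis=1).mean()) for c, g in groups.items()
    ]
    classes = labels.classes
    separations = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            if between == "centroid":
                separations.append(
                    float(np.linalg.norm(centroids[classes[i]] - centroids[classes[j]]))
                )
            else:
                separations.append(
                    float(cdist(groups[classes[i]], groups[classes[j]]).min())
                )
    return min(separations) / max(max(spreads), epsilon)


def _make_classifier(name: str, seed: int):
    """Standard classifiers consumed as components; hyperparameters are the defaults
    k=5 (kNN) and a linear kernel with C=1 (SVM)."""
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValidationError(f"unknown classifier {name!r}")


def cross_validate(
    coordinates: np.ndarray,
    labels: LabelVector,
    classifier: str = "knn",
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified k-fold CV accuracy: (mean, population variance across folds)."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim == 1:
        coordinates = coordinates[:, None]
    if not isinstance(labels, LabelVector):
        labels = LabelVector(labels)
    labels.check_alignment(coordinates.shape[0])
    labels.require_multiclass()
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    y = labels.labels.astype(str)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValidationError(
            f"smallest class has {counts.min()} members; stratified "
            f"{folds}-fold CV needs every class to have >= folds members"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accuracies = []
    for train, test in skf.split(coordinates, y):
        clf = _make_classifier(classifier, seed)
        clf.fit(coordinates[train], y[train])
        accuracies.append(float(np.mean(clf.predict(coordinates[test]) == y[test])))
    accuracies = np.asarray(accuracies)
    return float(accuracies.mean()), float(accuracies.var())


def trapezoid_aggregate(curve: dict[int, float]) -> float:
    """Trapezoidal integral of an accuracy-vs-components curve, normalized by
    the component range so a constant curve maps to its own value."""
    if len(curve) < 2:
        raise ValidationError("trapezoid aggregation needs at least 2 curve points")
    xs = np.array(sorted(curve), dtype=float)
    ys = np.array([curve[int(x)] for x in xs], dtype=float)
    return float(np.trapezoid(ys, xs) / (xs[-1] - xs[0]))


def roc_curve(scores: np.ndarray, labels: LabelVector):
    """ROC points and AUC. Binary scores give one curve; multiclass score
    matrices are handled one-vs-rest with macro-averaged AUC."""
    if not isinstance(labels, LabelVector):
        labels = LabelVector(labels)
    labels.require_multiclass()
    scores = np.asarray(scores, dtype=float)
    y = labels.labels.astype(str)
    classes = labels.classes
    if scores.ndim == 1:
        if len(classes) != 2:
            raise ValidationError("1-D scores require a binary task")
        positive = classes[1]
        fpr, tpr, _ = _sk_roc_curve((y == positive).astype(int), scores)
        return {positive: (fpr, tpr)}, float(_sk_auc(fpr, tpr))
    if scores.shape[1] != len(classes):
        raise ValidationError(
            f"score matrix has {scores.shape[1]} columns for {len(classes)} classes"
        )
    points, aucs = {}, []
    for j, c in enumerate(classes):
        fpr, tpr, _ = _sk_roc_curve((y == c).astype(int), scores[:, j])
        points[c] = (fpr, tpr)
        aucs.append(_sk_auc(fpr, tpr))
    return points, float(np.mean(aucs))


def cv_scores(
    coordinates: np.ndarray,
    labels: LabelVector,
    classifier: str = "knn",
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cross-validated class scores (n_samples x n_classes) for ROC analysis."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim == 1:
        coordinates = coordinates[:, None]
    if not isinstance(labels, LabelVector):
        labels = LabelVector(labels)
    y = labels.labels.astype(str)
    clf = _make_classifier(classifier, seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    method = "predict_proba" if classifier == "knn" else "decision_function"
    scores = cross_val_predict(clf, coordinates, y, cv=skf, method=method)
    if scores.ndim == 1:  # binary decision_function -> two-column convention
        scores = np.column_stack([-scores, scores])
    return scores


def accuracy_curve(
    sample_coordinates: np.ndarray, labels: LabelVector, classifier: str, config: RunConfig
) -> tuple[dict[int, tuple[float, float]], dict[int, float]]:
    """CV accuracy and Dunn Index for every component count in the config range.

    Truncating a classical-MDS embedding to its leading c components equals
    re-embedding at c components, so one cached embedding serves the whole
    sweep.
    """
    sample_coordinates = np.asarray(sample_coordinates, dtype=float)
    max_c = min(config.n_components_max, sample_coordinates.shape[1])
    if max_c < config.n_components_min:
        raise ValidationError(
            f"embedding has {sample_coordinates.shape[1]} components, fewer than "
            f"n_components_min={config.n_components_min}"
        )
    acc: dict[int, tuple[float, float]] = {}
    dunn: dict[int, float] = {}
    for c in range(config.n_components_min, max_c + 1):
        coords_c = sample_coordinates[:, :c]
        acc[c] = cross_validate(
            coords_c, labels, classifier, config.cv_folds, config.random_seed
        )
        dunn[c] = dunn_index(coords_c, labels)
    return acc, dunn


def evaluate_embedding(
    sample_coordinates: np.ndarray, labels: LabelVector, config: RunConfig
) -> EvaluationReport:
    """Full evaluation report: curves, trapezoid aggregate, and per-classifier AUC."""
    if not isinstance(labels, LabelVector):
        labels = LabelVector(labels)
    acc, dunn = accuracy_curve(sample_coordinates, labels, config.classifier, config)
    aggregate = trapezoid_aggregate({c: m for c, (m, _) in acc.items()}) if len(acc) > 1 else (
        next(iter(acc.values()))[0]
    )
    aucs = {}
    for clf in ("knn", "svm", "lda"):
        scores = cv_scores(
            sample_coordinates, labels, clf, config.cv_folds, config.random_seed
        )
        _, aucs[clf] = roc_curve(scores, labels)
    return EvaluationReport(
        dunn_by_components=dunn,
        accuracy_by_components=acc,
        aggregate_accuracy=aggregate,
        auc=aucs,
        config=config.to_dict(),
    )


def sigma_sweep(
    X: GeneExpressionMatrix,
    pathways: PathwayCollection,
    labels: LabelVector,
    sigma_grid,
    config: RunConfig,
    n_components: int | None = None,
) -> tuple[dict[float, float], float]:
    """Dunn Index of the pathway-weighted embedding for each sigma on the grid.

    Replicates the selection-by-Dunn-Index procedure for the weight learning
    parameter: the Jaccard matrix, covariance, and base Mahalanobis distances
    are computed once, only the weights change per sigma. Returns the mapping
    and the argmax sigma.
    """
    sigma_grid = [float(s) for s in sigma_grid]
    if not sigma_grid:
        raise ValidationError("sigma grid must be non-empty")
    if not isinstance(labels, LabelVector):
        labels = LabelVector(labels)
    labels.check_alignment(X.n_samples)
    if n_components is None:
        n_components = config.n_components_min
    gene_pathways = pathway_sets_per_gene(pathways, X.gene_ids)
    J = jaccard_matrix(gene_pathways)
    cov = estimate_covariance(X, config.covariance_regularization)
    base = mahalanobis_distance_matrix(X, cov)
    results: dict[float, float] = {}
    for sigma in sigma_grid:
        W = weight_matrix(J, sigma)
        weighted = base / W.values
        np.fill_diagonal(weighted, 0.0)
        emb = _embed_distance_matrix(weighted, config, X.gene_ids)
        coords = project_samples(emb, X)[:, :n_components]
        results[sigma] = dunn_index(coords, labels)
    best = max(results, key=lambda s: (results[s], -s))
    return results, best
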