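"""Core in-memory containers: expression matrix, pathway sets, labels, config.

The expression matrix is oriented genes x samples throughout the package
(the manifold is learned in gene space; samples are projected onto it
afterwards). Orientation is never guessed from shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class GeneExpressionMatrix:
    """Real-valued expression values, genes in rows, samples in columns.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values on an arbitrary scale.
    gene_ids : sequence of str
        Unique row identifiers, order preserved.
    sample_ids : sequence of str
        Unique column identifiers, order preserved.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes < 2 or n_samples < 2:
            raise ValidationError(
                f"need at least 2 genes and 2 samples, got {n_genes} x {n_samples}"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValidationError(f"duplicate {name} ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GeneExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PathwayCollection:
    """Named gene sets (pathway name -> member gene ids).

    Membership is pure set semantics; pathway topology is not represented.
    """

    sets: dict[str, frozenset[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            members = frozenset(str(m) for m in members)
            if not members:
                raise ValidationError(f"pathway {name!r} has no members")
            clean[str(name)] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass
class LabelVector:
    """One categorical class label per sample, aligned to sample order."""

    labels: np.ndarray

    def __init__(self, labels: Sequence) -> None:
        self.labels = np.asarray([str(x) for x in labels], dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def require_multiclass(self) -> None:
        if len(self.classes) < 2:
            raise ValidationError(
                "evaluation requires at least 2 distinct class labels, got "
                f"{self.classes}"
            )

    def check_alignment(self, n_samples: int) -> None:
        if len(self) != n_samples:
            raise ValidationError(
                f"{len(self)} labels for {n_samples} samples"
            )


@dataclass
class RunConfig:
    """Run parameters for embedding and evaluation.

    sigma is the learning parameter of the pathway weights w = exp(sigma * J):
    sigma = 0 disables the prior entirely (plain Isomap), larger sigma pulls
    genes sharing pathways exponentially closer.
    """

    k_neighbors: int = 10
    sigma: float = 1.0
    n_components_min: int = 2
    n_components_max: int = 50
    shortest_path_algorithm: str = "dijkstra"
    covariance_regularization: float | None = None  # None -> 1e-3 * mean diag
    random_seed: int = 0
    classifier: str = "knn"
    cv_folds: int = 10
    largest_component: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be >= 1")
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        if not (2 <= self.n_components_min <= self.n_components_max):
            raise ValidationError(
                "need 2 <= n_components_min <= n_components_max, got "
                f"[{self.n_components_min}, {self.n_components_max}]"
            )
        if self.shortest_path_algorithm not in ("dijkstra", "floyd_warshall"):
            raise ValidationError(
                f"unknown shortest_path_algorithm {self.shortest_path_algorithm!r}"
            )
        if self.covariance_regularization is not None and self.covariance_regularization < 0:
            raise ValidationError("covariance_regularization must be non-negative")
        if self.classifier not in ("knn", "svm", "lda"):
            raise ValidationError(f"unknown classifier {self.classifier!r}")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    def validate_for(self, n_genes: int) -> None:
        """Check the constraints that depend on the data size."""
        if not self.k_neighbors < n_genes:
            raise ValidationError(
                f"k_neighbors={self.k_neighbors} must be < n_genes={n_genes}"
            )
        if not self.n_components_max < n_genes:
            raise ValidationError(
                f"n_components_max={self.n_components_max} must be < n_genes={n_genes}"
            )

    def to_dict(self) -> dict:
        return {
            "k_neighbors": self.k_neighbors,
            "sigma": self.sigma,
            "n_components_min": self.n_components_min,
            "n_components_max": self.n_components_max,
            "shortest_path_algorithm": self.shortest_path_algorithm,
            "covariance_regularization": self.covariance_regularization,
            "random_seed": self.random_seed,
            "classifier": self.classifier,
            "cv_folds": self.cv_folds,
            "largest_component": self.largest_component,
        }
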