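"""Pathway prior: Jaccard co-membership similarity and the exponential weights.

Two genes are similar under the prior to the degree that they belong to the
same pathways: J(a, b) = |P_a n P_b| / |P_a u P_b| where P_g is the set of
pathways containing gene g. The weight w = exp(sigma * J) then divides the
expression-space distance downstream, pulling co-pathway genes closer in the
neighbourhood graph. sigma = 0 makes every weight 1 (no prior).

Two genes with no pathway annotations at all get J = 0, not 1: absence of
annotation carries no evidence of relatedness, and this convention makes
"remove all pathways" collapse exactly onto plain Isomap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import PathwayCollection
from .errors import ValidationError


@dataclass
class JaccardMatrix:
    """Symmetric gene-by-gene pathway co-membership similarity, entries in [0, 1]."""

    values: np.ndarray
    gene_ids: list[str]


@dataclass
class WeightMatrix:
    """Symmetric gene-by-gene weights w = exp(sigma * J); every entry >= 1."""

    values: np.ndarray
    sigma: float
    gene_ids: list[str]


def jaccard(set_a, set_b) -> float:
    """Jaccard coefficient |A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def pathway_sets_per_gene(
    pathways: PathwayCollection, gene_ids
) -> dict[str, frozenset[str]]:
    """Invert pathway -> members into gene -> pathways, over the given gene order.

    Every gene in ``gene_ids`` gets an entry, possibly empty. Pathway members
    absent from ``gene_ids`` are ignored.
    """
    gene_ids = [str(g) for g in gene_ids]
    wanted = set(gene_ids)
    memberships: dict[str, set[str]] = {g: set() for g in gene_ids}
    for name, members in pathways.sets.items():
        for gene in members:
            if gene in wanted:
                memberships[gene].add(name)
    return {g: frozenset(s) for g, s in memberships.items()}


def jaccard_matrix(gene_pathways: dict[str, frozenset[str]]) -> JaccardMatrix:
    """All-pairs Jaccard over the genes' pathway sets, in the mapping's order.

    Vectorized through the boolean gene x pathway membership matrix:
    intersections are an integer matrix product, unions follow by
    inclusion-exclusion.
    """
    gene_ids = list(gene_pathways)
    n = len(gene_ids)
    pathway_names = sorted({p for s in gene_pathways.values() for p in s})
    if not pathway_names:
        values = np.zeros((n, n))
        np.fill_diagonal(values, 1.0)
        return JaccardMatrix(values, gene_ids)
    col = {p: j for j, p in enumerate(pathway_names)}
    membership = np.zeros((n, len(pathway_names)), dtype=np.int64)
    for i, g in enumerate(gene_ids):
        for p in gene_pathways[g]:
            membership[i, col[p]] = 1
    inter = membership @ membership.T
    sizes = membership.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(values, 1.0)  # diagonal never consumed (no self-edges)
    return JaccardMatrix(values, gene_ids)


def weight_matrix(J: JaccardMatrix, sigma: float) -> WeightMatrix:
    """Exponential weights w[i,j] = exp(sigma * J[i,j]).

    sigma = 0 gives the all-ones (neutral) matrix. Large sigma * J is computed
    with a clipped exponent so the weights saturate at the float maximum
    instead of overflowing to inf.
    """
    if sigma < 0:
        raise ValidationError(f"sigma must be non-negative, got {sigma}")
    exponent = sigma * J.values
    # keep exp() inside float range; distances divided by such weights -> ~0
    max_exp = np.log(np.finfo(float).max) - 1.0
    values = np.exp(np.minimum(exponent, max_exp))
    return WeightMatrix(values, float(sigma), J.gene_ids)
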