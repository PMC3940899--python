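"""Pathway-dropout robustness: remove pathways at random and re-run the method.

Each pathway is retained independently with probability 1 - p; at p = 0 the
experiment reproduces the full-prior run, at p = 1 it reproduces plain Isomap
(the empty prior is exactly neutral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GeneExpressionMatrix, LabelVector, PathwayCollection, RunConfig
from .errors import ValidationError
from .evaluation import cv_scores, dunn_index, roc_curve
from .manifold import apriori_isomap, project_samples


@dataclass
class RobustnessResult:
    """Mean and spread of Dunn Index and AUC per removal probability."""

    removal_probabilities: list[float]
    retained_counts: dict[float, list[int]]
    dunn: dict[float, list[float]]
    auc: dict[float, list[float]]
    n_replicates: int
    seed: int
    n_components: int = 2
    summary: dict = field(default_factory=dict)

    def summarize(self) -> dict:
        out = {}
        for p in self.removal_probabilities:
            out[p] = {
                "retained_mean": float(np.mean(self.retained_counts[p])),
                "dunn_mean": float(np.mean(self.dunn[p])),
                "dunn_sd": float(np.std(self.dunn[p])),
                "auc_mean": float(np.mean(self.auc[p])),
                "auc_sd": float(np.std(self.auc[p])),
            }
        self.summary = out
        return out


def drop_pathways(pathways: PathwayCollection, p: float, seed: int) -> PathwayCollection:
    """Retain each pathway independently with probability 1 - p."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"removal probability must lie in [0, 1], got {p}")
    if p == 0.0:
        return PathwayCollection(dict(pathways.sets), source_tag=pathways.source_tag)
    if p == 1.0:
        return PathwayCollection({}, source_tag=pathways.source_tag)
    rng = np.random.default_rng(seed)
    kept = {
        name: members
        for name, members in pathways.sets.items()
        if rng.random() >= p
    }
    return PathwayCollection(kept, source_tag=pathways.source_tag)


def robustness_experiment(
    X: GeneExpressionMatrix,
    pathways: PathwayCollection,
    labels: LabelVector,
    probabilities,
    replicates: int,
    config: RunConfig,
    n_components: int | None = None,
) -> RobustnessResult:
    """Dunn Index and AUC of the pathway-weighted embedding under dropout.

    For each removal probability, ``replicates`` independent dropout draws
    (seeds derived from ``config.random_seed``) are embedded and evaluated at
    ``n_components`` components (default: config.n_components_min).
    """
    if not isinstance(labels, LabelVector):
        labels = LabelVector(labels)
    labels.check_alignment(X.n_samples)
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    probabilities = sorted(float(p) for p in probabilities)
    if n_components is None:
        n_components = config.n_components_min
    ss = np.random.SeedSequence([int(config.random_seed), 2])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(replicates)]
    result = RobustnessResult(
        removal_probabilities=probabilities,
        retained_counts={p: [] for p in probabilities},
        dunn={p: [] for p in probabilities},
        auc={p: [] for p in probabilities},
        n_replicates=replicates,
        seed=config.random_seed,
        n_components=n_components,
    )
    for p in probabilities:
        for rep in range(replicates):
            dropped = drop_pathways(pathways, p, child_seeds[rep])
            emb = apriori_isomap(X, dropped, config)
            coords = project_samples(emb, X)[:, :n_components]
            result.retained_counts[p].append(len(dropped))
            result.dunn[p].append(dunn_index(coords, labels))
            scores = cv_scores(
                coords, labels, config.classifier, config.cv_folds, config.random_seed
            )
            _, auc_val = roc_curve(scores, labels)
            result.auc[p].append(auc_val)
    result.summarize()
    return result
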