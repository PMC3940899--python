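# Methods

## Model and procedure

`pwisomap` learns a nonlinear manifold in **gene space**: each gene's
expression profile across samples is one point in R^{n_samples}, and the
gene-by-gene affinity structure — not the sample-by-sample one — is what the
pathway prior can inform, because curated pathways describe relations
between genes. The pipeline is

1. **Jaccard co-membership.** For every gene pair, J = |P_i ∩ P_j| / |P_i ∪ P_j|
   over the genes' pathway sets. J(∅, ∅) is defined as 0, not 1: missing
   annotation is absence of evidence, and this convention makes the empty
   prior exactly neutral. The J diagonal is stored as 1 by convention but is
   never consumed (the neighbourhood graph has no self-edges).
2. **Weights.** w = exp(σ·J). The exponential form is used because the
   learning parameter's effect is meant to be exponential in the prior
   similarity; the weight function is a single code path that alternative
   forms could replace. Exponents are clipped at the float-safe maximum so
   extreme σ saturates instead of overflowing.
3. **Base metric.** Mahalanobis distance between gene profiles. The
   covariance of the sample-space coordinates is estimated over genes as
   observations and is singular whenever coordinates are collinear, so a
   ridge term is added to the diagonal before Cholesky inversion (default
   1e-3 × mean diagonal; zero ridge on a singular matrix raises an explicit
   error naming the remedy).
4. **Weighted metric.** d = d_Mahalanobis / w. Weights are ≥ 1, so sharing
   pathways can only shrink a distance; w = 1 leaves it untouched. The
   division (rather than a modification inside the quadratic form) directly
   implements "genes sharing pathways should be more likely to be
   neighbours" and keeps neutrality exact.
5. **Graph and geodesics.** k-nearest-neighbour graph, ties broken by lower
   node index, symmetrized by edge union (standard k-Isomap). Shortest paths
   by Dijkstra (default) or Floyd–Warshall via `scipy.sparse.csgraph`; both
   agree to floating tolerance and are cross-checked in tests against
   networkx. A disconnected graph is a hard error reporting component sizes;
   an opt-in fallback (`largest_component`) embeds the largest component and
   marks dropped genes with NaN coordinates. Zero-length edges between
   duplicate points are kept with the smallest positive float so the sparse
   routines do not drop them.
6. **Classical MDS.** B = −½ H D_G² H with H = I − 11ᵀ/n; dense symmetric
   eigendecomposition below 2000 nodes, ARPACK above (requested components
   plus a 10-vector buffer). Geodesic matrices are generally non-Euclidean,
   so negative eigenvalues occur and are discarded; coordinates use only
   positive eigenvalues (√λ·v). Each eigenvector's sign is fixed so its
   largest-magnitude entry is positive, making repeated runs bit-identical.
   The pipeline caps the returned component count at the number of positive
   eigenvalues when the configured maximum exceeds it; `classical_mds`
   itself is strict and raises.
7. **Sample projection.** Sample coordinates are Xᵀ·Y with Y the √λ-scaled
   gene basis. The scaling convention is recorded in the run manifest; it
   affects only the relative weighting of components, and the evaluation
   metrics used here (Dunn ratio, CV accuracy) are insensitive to a global
   per-component rescaling of this kind in practice.

## Evaluation protocol

- **Dunn Index**: minimum over cluster pairs of centroid-to-centroid
  distance, divided by the maximum over clusters of the mean distance of
  members to their centroid; labels act as clusters. Centroid linkage is
  used for the numerator to match the centroid-based denominator;
  single-linkage is available as an option. A zero denominator (all
  singleton or duplicated clusters) is guarded by ε = 1e-12, which makes the
  degenerate value finite and comparable.
- **Cross-validation**: stratified k-fold (default 10), shuffled under the
  run seed; the variance reported is the population variance of the fold
  accuracies. Stratification protects small classes in imbalanced designs.
  Classifiers are consumed as standard components from scikit-learn: kNN
  (k = 5), linear-kernel SVM (C = 1), and LDA — the method under study never
  depends on their internals.
- **Trapezoidal aggregation**: the accuracy-vs-components curve (default
  range 2–50 components) is integrated with the trapezoid rule and
  normalized by the component range so a constant curve maps to its own
  value and results stay in [0, 1].
- **ROC/AUC**: binary tasks directly; multiclass one-vs-rest with
  macro-averaged AUC. Scores come from cross-validated predicted
  probabilities (kNN) or decision functions (SVM, LDA).
- **σ selection**: embed per candidate σ and keep the Dunn-maximizing value.
  The Jaccard matrix, covariance, and base distances are computed once per
  sweep; only the weights change. σ is dataset-specific — on real tumour
  data with sparse annotation the selected value can be in the tens of
  thousands, while the dense synthetic prior saturates near σ ≈ 1–5 — so the
  package ships σ = 1 as a neutral default and expects the sweep to choose.
- **Pathway dropout**: each pathway kept independently with probability
  1 − p; 10 dropout draws per p (seeds derived from the run seed via
  `SeedSequence`) with mean ± sd reported. p = 0 reproduces the full-prior
  run and p = 1 reproduces plain Isomap exactly, because an empty collection
  gives J ≡ 0 off-diagonal and hence w ≡ 1.

## Synthetic data

The generator emulates the statistical structure the method assumes, at desk
scale: 120 genes × 80 samples by default (the real studies this emulates run
at ~10⁴ genes; the mechanism under test does not depend on that scale).
Samples get latent coordinates (class centroid + unit Gaussian noise;
centroids on distinct latent axes at separation 4), pushed through a
nonlinearity (identity, swiss roll, or S-curve; S-curve default) into
standardized manifold factor profiles. Two thirds of the genes read out
exactly one factor with a positive gain in [0.75, 1.25] — these gene blocks
are the "co-informative" groups — and one third are background noise genes.
All genes get a constant baseline offset (sd 0.5) and additive Gaussian
noise, sd 1.0 by default, i.e. SNR ≈ 1 on informative genes, a realistic
microarray regime and the regime in which a prior has something to add:
with this noise the Mahalanobis gene neighbourhoods are unreliable on their
own (the estimated covariance partially whitens away the very factor
directions that carry the signal), and pathway weighting restores them.
Pathways (30 sets of 5–15 genes) are drawn from inside a single gene block
with probability `alignment`, else uniformly — so `alignment` is exactly the
degree to which pathway co-membership correlates with co-informativeness.

What passing tests on this generator show: the weighting mechanism extracts
exactly the signal placed in the pathway sets, helps when that signal aligns
with class-informative structure, and is inert when it does not. What they
do not show: performance under real microarray artefacts (probe saturation,
batch effects, heavy-tailed noise), under annotation bias of real KEGG
snapshots, or at 10⁴-gene scale.

## Numerical and design choices

- All randomness flows from explicit seeds (`RunConfig.random_seed`,
  `SyntheticSpec.seed`); derived seeds use `numpy.random.SeedSequence` and
  stay below 2³¹. Identical inputs give byte-identical outputs.
- Expression orientation is genes × rows, never guessed; mismatched inputs
  fail on identifier checks.
- kNN ties: lower index wins. ε-radius neighbourhoods and landmark
  acceleration are out of scope.
- Genes absent from every pathway are kept with empty pathway sets (J = 0
  against everything), so adding an irrelevant GMT cannot change an
  embedding.
- The experiments in `examples/` and `scripts/acceptance.py` use σ = 5 for
  the weighted arm: far enough from neutrality that weight ratios
  (exp(5·J) up to ~150) can reorder noisy neighbourhoods, while the
  σ-selection example shows the Dunn-optimal value near 1–5 on the default
  synthetic prior.
- Plain-Isomap baselines use the Euclidean metric by default (the classic
  algorithm); comparisons against the weighted method use the Mahalanobis
  metric for both arms so the pathway weighting is the only difference.

## Known limitations

- The gene-space formulation scales quadratically in gene count (Jaccard and
  distance matrices are n_genes²); at 10⁴ genes the Jaccard matrix is the
  dominant cost and should be cached (delimited text export is supported).
- The ridge covariance is a crude estimator when samples ≫ genes is
  violated; shrinkage estimators would be a natural extension.
- Dunn Index degenerates with singleton clusters; the ε guard makes the
  value finite but such comparisons should be read qualitatively.
- The sample projection assumes the raw data matrix is meaningful in the
  gene basis; heavily normalized or rank-transformed inputs change its
  interpretation.
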