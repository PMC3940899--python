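# pwisomap — pathway-weighted Isomap for gene-expression manifolds

High-dimensional expression matrices (microarray or RNA-seq, thousands of
gene probes, modest sample counts) are noisy, and the samples are widely
believed to lie near a low-dimensional nonlinear manifold. Isomap recovers
such a manifold from the data alone: connect each point to its *k* nearest
neighbours, take shortest-path (geodesic) distances on that graph, and embed
them with classical multidimensional scaling. `pwisomap` implements a
prior-knowledge variant for transcriptomics: curated pathway gene sets
(e.g. KEGG, supplied as a GMT file) reshape the metric in **gene space**
before the neighbourhood graph is built, so that genes sharing biological
pathways are more likely to become neighbours on the manifold. The prior is
used only to find the space; classification afterwards runs on the projected
raw data and is never biased by it.

## The method

For genes *i*, *j* with pathway sets *P<sub>i</sub>*, *P<sub>j</sub>*:

- pathway similarity: Jaccard coefficient
  *J<sub>ij</sub>* = |*P<sub>i</sub>* ∩ *P<sub>j</sub>*| / |*P<sub>i</sub>* ∪ *P<sub>j</sub>*|
  (defined as 0 when both sets are empty);
- weights: *w<sub>ij</sub>* = exp(σ·*J<sub>ij</sub>*), with σ ≥ 0 a learning
  parameter selected by maximizing the Dunn Index;
- base metric: Mahalanobis distance
  *d<sub>M</sub>*(*x<sub>i</sub>*, *x<sub>j</sub>*) = √((*x<sub>i</sub>*−*x<sub>j</sub>*)ᵀS⁻¹(*x<sub>i</sub>*−*x<sub>j</sub>*))
  between gene expression profiles, with a ridge-regularized covariance S;
- weighted metric: *d<sub>ij</sub>* = *d<sub>M</sub>* / *w<sub>ij</sub>* —
  genes sharing pathways are pulled exponentially closer;
- embedding: k-nearest-neighbour graph under *d*, geodesics by Dijkstra or
  Floyd–Warshall, then classical MDS: eigendecompose
  B = −½ H D<sub>G</sub>² H and set component *i* to √λ<sub>i</sub>·v<sub>i</sub>;
- sample projection: the sample-space coordinates are Xᵀ·Y, where Y is the
  √λ-scaled gene-space eigenbasis.

σ = 0, an empty GMT, or pathways disjoint from the matrix all reduce the
method *exactly* to plain Isomap. Evaluation utilities cover the Dunn Index
(min centroid separation over max mean within-cluster spread), stratified
k-fold CV accuracy curves over component counts with trapezoidal
aggregation, ROC/AUC with kNN, linear SVM and LDA, σ selection, and a
pathway-dropout robustness experiment. A synthetic-data generator produces
manifold-structured expression matrices with pathway sets whose
co-membership aligns (tunably) with gene co-informativeness, so the whole
pipeline is testable without external downloads.

## Worked example

```sh
python examples/embed_synthetic.py
```

```
Dunn Index, pathway-weighted Isomap : 2.778
Dunn Index, plain Isomap            : 1.379
```

A 120-gene × 80-sample synthetic dataset with two classes is embedded twice
from the same Mahalanobis base metric; the only difference is the pathway
weighting (σ = 5). The weighted embedding's 2-component Dunn Index is about
twice plain Isomap's: the prior pulled co-informative genes together, and
projecting the samples onto that manifold produced denser, better-separated
class clusters. The other examples show the paired 20-replicate comparison
(`prior_vs_plain.py`: prior wins 19/20 aligned replicates, chance-level when
pathways are uninformative), σ selection by Dunn Index
(`sigma_selection.py`), and the dropout experiment (`pathway_dropout.py`).

The same pipeline is available from the shell:

```sh
pwisomap simulate --n-genes 120 --n-samples 80 --seed 0 --out data/
pwisomap embed --expression data/expression.tsv --gmt data/pathways.gmt \
    --sigma 5 --n-components-max 10 --out run/
pwisomap evaluate --expression data/expression.tsv --labels data/labels.tsv \
    --gmt data/pathways.gmt --sigma 5 --n-components-max 10 --out eval/
pwisomap robustness --expression data/expression.tsv --labels data/labels.tsv \
    --gmt data/pathways.gmt --sigma 5 --n-components-max 10 --out rob/
```

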