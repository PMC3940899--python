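"""Embed a synthetic expression matrix with and without the pathway prior.

Generates a 120-gene x 80-sample dataset whose samples sit near a noisy
2-D manifold with two classes, plus 30 pathway gene sets aligned with the
informative gene blocks. Both embeddings are built in gene space; samples
are projected onto the manifold afterwards, and the Dunn Index (higher =
denser, better-separated class clusters) is compared at 2 components.
"""

import pwisomap as pw

data = pw.generate_dataset(pw.SyntheticSpec(seed=0))
config = pw.RunConfig(k_neighbors=10, sigma=5.0, n_components_max=10)

weighted = pw.apriori_isomap(data.expression, data.pathways, config)
plain = pw.plain_isomap(data.expression, config, metric="mahalanobis")

coords_weighted = pw.project_samples(weighted, data.expression)[:, :2]
coords_plain = pw.project_samples(plain, data.expression)[:, :2]

dunn_weighted = pw.dunn_index(coords_weighted, data.labels)
dunn_plain = pw.dunn_index(coords_plain, data.labels)

print(f"Dunn Index, pathway-weighted Isomap : {dunn_weighted:.3f}")
print(f"Dunn Index, plain Isomap            : {dunn_plain:.3f}")
print(
    "A larger value for the weighted embedding means the pathway prior "
    "pulled co-informative genes together and produced denser sample clusters."
)
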