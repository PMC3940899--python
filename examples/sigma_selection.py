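"""Select the weight learning parameter sigma by maximizing the Dunn Index.

The weights w = exp(sigma * J) interpolate between no prior (sigma = 0) and a
prior that dominates the expression metric. The standard selection procedure
embeds the data for each candidate sigma and keeps the value with the highest
Dunn Index of the projected samples. On real tumour data the selected value
can be very large (tens of thousands) because annotated gene pairs are sparse;
on this dense synthetic prior a small sigma already saturates the benefit.
"""

import pwisomap as pw

data = pw.generate_dataset(pw.SyntheticSpec(seed=0))
config = pw.RunConfig(k_neighbors=10, n_components_max=10)

grid = [0.0, 1.0, 2.0, 5.0, 10.0, 20.0]
results, best = pw.sigma_sweep(
    data.expression, data.pathways, data.labels, grid, config
)

for sigma in grid:
    marker = "  <- selected" if sigma == best else ""
    print(f"sigma = {sigma:5.1f}: Dunn Index = {results[sigma]:.3f}{marker}")
print(
    "The selected sigma maximizes cluster density of the projected samples; "
    "sigma = 0 reproduces plain Isomap and serves as the no-prior baseline."
)
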