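"""Paired replicate comparison: does the pathway prior create denser clusters?

Runs 20 independent synthetic datasets at pathway-class alignment 0.8 and 20
at alignment 0 (pathways drawn uniformly, carrying no information). For each,
the 2-component Dunn Index of the weighted embedding is compared with plain
Isomap on the same data. With aligned pathways the prior should win almost
every replicate; with unaligned pathways the sign test should be
non-significant.
"""

import pwisomap as pw

config = pw.RunConfig(k_neighbors=10, sigma=5.0, n_components_max=10)

aligned = pw.prior_benefit_replicates(
    pw.SyntheticSpec(alignment=0.8, seed=0), config, n_replicates=20
)
null = pw.prior_benefit_replicates(
    pw.SyntheticSpec(alignment=0.0, seed=0), config, n_replicates=20
)

print(
    f"alignment 0.8: prior wins {aligned['wins']}/20 replicates "
    f"(sign test p = {aligned['sign_test_p']:.2g})"
)
print(
    f"alignment 0.0: prior wins {null['wins']}/20 replicates "
    f"(sign test p = {null['sign_test_p']:.2g})"
)
print(
    "Wins near 20/20 under alignment and a large p-value under the null mean "
    "the benefit comes from the biological signal in the pathways, not from "
    "the weighting machinery itself."
)
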