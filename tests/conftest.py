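import numpy as np
import pytest

from pwisomap import (
    GeneExpressionMatrix,
    PathwayCollection,
    RunConfig,
    SyntheticSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig(k_neighbors=10, sigma=5.0, n_components_max=10)


@pytest.fixture(scope="session")
def aligned_dataset():
    """Default synthetic dataset: aligned pathways, class-structured samples."""
    return generate_dataset(SyntheticSpec(seed=0))


@pytest.fixture()
def tiny_matrix() -> GeneExpressionMatrix:
    rng = np.random.default_rng(42)
    values = rng.normal(size=(20, 8))
    return GeneExpressionMatrix(
        values, [f"G{i}" for i in range(20)], [f"S{j}" for j in range(8)]
    )


@pytest.fixture()
def toy_pathways() -> PathwayCollection:
    return PathwayCollection(
        {"P1": {"G1", "G2"}, "P2": {"G2", "G3"}, "P3": {"G0", "G1", "G2"}}
    )
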