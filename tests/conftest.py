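import numpy as np
import pytest

from scselect import GeneratorConfig, generate, lognormalize

# tiny grid for the downstream random forest in tests where the paper-scale
# grid would only add runtime, not coverage
FAST_GRID = {
    "pca__n_components": [10],
    "rf__max_features": [4],
    "rf__n_estimators": [50],
}


@pytest.fixture(scope="session")
def small_rna():
    """400-cell, 200-gene three-type RNA dataset with true markers."""
    cfg = GeneratorConfig(
        n_cells=400, n_genes=200,
        proportions={"A": 0.5, "B": 0.3, "C": 0.2},
        marker_effect=3.0, seed=11,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_rna_lognorm(small_rna):
    ds, truth, spec = small_rna
    return lognormalize(ds), truth, spec


@pytest.fixture(scope="session")
def small_cytof():
    cfg = GeneratorConfig(
        n_cells=300, n_genes=39,
        proportions={"A": 0.4, "B": 0.35, "C": 0.25},
        markers_per_type=2, program_genes_per_type=5,
        marker_effect=2.0, modality="cytof", seed=5,
    )
    return generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
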