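import numpy as np
import pytest

from spotsom import synthetic
from spotsom.preprocess import preprocess
from spotsom.som import SomPortrayal

SMALL = synthetic.SyntheticConfig(
    n_rows=10, n_cols=10, n_domains=3, genes_per_module=20,
    n_background_genes=100, seed=11,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale synthetic fixture: 10x10 lattice, 3 domains, 160 genes."""
    return synthetic.generate(SMALL)


@pytest.fixture(scope="session")
def small_centralized(small_dataset):
    matrix, _, _ = small_dataset
    return preprocess(matrix)


@pytest.fixture(scope="session")
def small_model(small_dataset, small_centralized):
    """An 8x8 SOM trained on the small fixture (shared; treat as read-only)."""
    return SomPortrayal(grid_rows=8, grid_cols=8, random_state=3).fit(small_centralized)


def model_from_weights(weights: np.ndarray, genes_per_unit: int = 1) -> SomPortrayal:
    """Hand-built fitted model: gene profiles sit exactly at unit weights."""
    weights = np.asarray(weights, dtype=float)
    rows, cols, n_spots = weights.shape
    model = SomPortrayal(grid_rows=rows, grid_cols=cols)
    gene_ids, assignment = [], []
    for r in range(rows):
        for c in range(cols):
            for g in range(genes_per_unit):
                gene_ids.append(f"g_r{r}c{c}_{g}")
                assignment.append((r, c))
    model._restore(
        weights=weights,
        gene_ids=gene_ids,
        spot_barcodes=[f"s{j}" for j in range(n_spots)],
        assignment=np.array(assignment),
        quantization_error=0.0,
        initial_quantization_error=0.0,
    )
    return model
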