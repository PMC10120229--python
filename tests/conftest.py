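import numpy as np
import pytest

from scbinary import (
    CountMatrix,
    SimConfig,
    binarize,
    normalize_log_cp10k,
    simulate_celltypes,
    simulate_multisample,
)


@pytest.fixture
def small_counts() -> CountMatrix:
    """4 genes x 3 cells with a mix of zeros and counts."""
    values = np.array(
        [
            [0, 3, 1],
            [2, 0, 0],
            [5, 1, 4],
            [0, 0, 2],
        ]
    )
    return CountMatrix(
        values=values,
        gene_ids=np.array([f"g{i}" for i in range(4)], dtype=object),
        cell_ids=np.array(["c0", "c1", "c2"], dtype=object),
    )


@pytest.fixture(scope="session")
def celltype_data():
    """Default multi-population dataset plus its marker truth table."""
    return simulate_celltypes(seed=42)


@pytest.fixture(scope="session")
def celltype_binary(celltype_data):
    return binarize(celltype_data[0])


@pytest.fixture(scope="session")
def celltype_normalized(celltype_data):
    return normalize_log_cp10k(celltype_data[0])


@pytest.fixture(scope="session")
def multisample_data():
    """Small two-condition multi-sample dataset with DE truth."""
    cfg = SimConfig(n_genes=400, samples_per_group=4, cells_per_sample=60, seed=7)
    return simulate_multisample(cfg)
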