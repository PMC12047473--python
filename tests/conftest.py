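import numpy as np
import pytest
from scipy import sparse

from iratri.preprocess import CountMatrix, normalize_log1p_cp10k
from iratri.synthetic_data import SimConfig, simulate_cohort


def dense_matrix(counts, genes=None, cells=None, normalized=False) -> CountMatrix:
    """CountMatrix from a dense genes x cells array, optionally normalized."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = genes if genes is not None else [f"g{i:03d}" for i in range(n_genes)]
    cells = cells if cells is not None else [f"c{i:03d}" for i in range(n_cells)]
    matrix = CountMatrix(genes=np.asarray(genes), cells=np.asarray(cells),
                         counts=sparse.csr_matrix(counts))
    return normalize_log1p_cp10k(matrix) if normalized else matrix


def continuous_matrix(rng, n_genes, n_cells) -> CountMatrix:
    """Matrix whose 'normalized' layer is dense continuous data (tie-free)."""
    values = rng.lognormal(0.0, 1.0, size=(n_genes, n_cells))
    matrix = CountMatrix(
        genes=np.array([f"g{i:04d}" for i in range(n_genes)]),
        cells=np.array([f"c{i:04d}" for i in range(n_cells)]),
        counts=sparse.csr_matrix(np.ones((n_genes, n_cells), dtype=int)),
    )
    matrix.normalized = sparse.csr_matrix(values)
    return matrix


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimConfig:
    return SimConfig(
        n_cancer_types=1,
        samples_per_group={"R": 4, "NR": 4, "pre": 2, "normal": 2},
        cells_per_sample=150,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_sim_config):
    return simulate_cohort(tiny_sim_config)
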