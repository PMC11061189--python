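import numpy as np
import pytest

from pedcns import synthetic_data as sd
from pedcns.preprocess import NormalizedMatrix


def make_normalized(matrix: np.ndarray, gene_names=None, cell_names=None) -> NormalizedMatrix:
    """Wrap an already-normalized matrix for modules that consume one."""
    n_cells, n_genes = matrix.shape
    return NormalizedMatrix(
        matrix=np.asarray(matrix, dtype=float),
        size_factors=np.ones(n_cells),
        gene_names=list(gene_names) if gene_names is not None else [f"g{i}" for i in range(n_genes)],
        cell_names=list(cell_names) if cell_names is not None else [f"c{i}" for i in range(n_cells)],
    )


@pytest.fixture(scope="session")
def small_pool():
    """A well-behaved 4-sample pool (1000 nuclei) with full staining."""
    cfg = sd.SimConfig(
        n_samples_per_pool=4,
        n_nuclei_per_sample=250,
        doublet_rate=0.05,
        hto_stain_efficiency=1.0,
        n_genes=120,
        program_size=20,
        n_mito_genes=10,
        seed=7,
    )
    genotypes = sd.simulate_genotypes(cfg)
    dataset, truth = sd.simulate_pool(cfg, genotypes)
    return cfg, genotypes, dataset, truth


@pytest.fixture(scope="session")
def confounded_data():
    """The default composition-confounded two-group dataset."""
    return sd.simulate_confounded_expression()
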