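import functools

import numpy as np
import pytest
import scipy.sparse as sp

import skinspace as ss
from skinspace.io import CountMatrix, merge_sections
from skinspace.qc import apply_qc, compute_qc_stats, normalize


@functools.lru_cache(maxsize=6)
def processed_experiment(seed: int):
    """Simulate the default three-condition experiment and run it through
    QC and normalization; cached per seed for reuse across tests."""
    cfg = ss.SimulationConfig(seed=seed)
    sections = ss.generate_dataset(cfg)
    counts, bins = merge_sections([(s.counts, s.bins) for s in sections])
    bins = compute_qc_stats(counts, bins)
    counts_qc, bins_qc = apply_qc(counts, bins)
    norm = normalize(counts_qc)
    return sections, counts_qc, bins_qc, norm


@pytest.fixture(scope="session")
def processed():
    return processed_experiment


def toy_counts(matrix, gene_names=None, barcodes=None) -> CountMatrix:
    matrix = np.asarray(matrix)
    n_genes, n_bins = matrix.shape
    gene_names = gene_names or [f"G{i}" for i in range(n_genes)]
    return CountMatrix(
        matrix=sp.csr_matrix(matrix),
        gene_ids=[f"ID{i}" for i in range(n_genes)],
        gene_names=gene_names,
        barcodes=barcodes or [f"B{i}" for i in range(n_bins)],
    )


@pytest.fixture
def make_counts():
    return toy_counts
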