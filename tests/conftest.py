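import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from svfcomm import (
    ClusterAssignment,
    CountMatrix,
    NormalizedMatrix,
    PlantedSignal,
    SimulationSpec,
    make_knowledge_tables,
    normalize,
    simulate_counts,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default 4-type synthetic SVF dataset (1,000 cells, 1,200 genes)."""
    return simulate_counts(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def planted_setup():
    """500 cells/type, one planted T0 -> T2 signal (fold 4/4, score 900)."""
    spec = SimulationSpec(
        seed=7,
        cells_per_type=500,
        n_genes=300,
        n_mito_genes=5,
        markers_per_type=10,
        qc_violator_fraction=0.0,
        planted_signals=(
            PlantedSignal("Gene0100", "Gene0200", "T0", "T2", 4.0, 4.0, 900),
        ),
    )
    data = simulate_counts(spec)
    lr, assoc = make_knowledge_tables(spec, n_decoys=8)
    nm = normalize(data.counts)
    return spec, data, nm, lr, assoc


def make_count_matrix(counts, barcodes=None, genes=None, is_mito=None) -> CountMatrix:
    counts = np.asarray(counts)
    n, g = counts.shape
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=pd.Index(barcodes or [f"c{i}" for i in range(n)]),
        gene_names=pd.Index(genes or [f"g{j}" for j in range(g)]),
        is_mito=is_mito,
    )


def make_normalized(values, barcodes=None, genes=None, scale_factor=1e6) -> NormalizedMatrix:
    """NormalizedMatrix with directly chosen log values (for formula tests)."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        barcodes=pd.Index(barcodes or [f"c{i}" for i in range(n)]),
        gene_names=pd.Index(genes or [f"g{j}" for j in range(g)]),
        scale_factor=scale_factor,
    )


def make_labels(labels, barcodes=None) -> ClusterAssignment:
    barcodes = barcodes or [f"c{i}" for i in range(len(labels))]
    return ClusterAssignment(pd.Series(list(labels), index=pd.Index(barcodes)))
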