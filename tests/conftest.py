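import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cyclegate import (
    CellByFeatureMatrix,
    Gene,
    GenomeModel,
    SimulationConfig,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def default_sim():
    """Full-default simulated experiment (5 x 600 cells), shared across
    tests; the seed is fixed once for the whole suite."""
    return simulate_experiment(SimulationConfig(seed=202))


@pytest.fixture()
def tiny_genome():
    return GenomeModel(
        chromosomes=[("chr1", 100_000), ("chr2", 50_000)],
        genes=[
            Gene("gA", "chr1", "+", 10_000, 10_000, 15_000),
            Gene("gB", "chr1", "-", 40_000, 35_000, 40_000),
            Gene("gM", "chr2", "+", 5_000, 5_000, 8_000),
        ],
        mito_gene_ids=frozenset({"gM"}),
    )


@pytest.fixture()
def small_counts():
    """4 cells x 3 features with known totals."""
    X = sp.csr_matrix(np.array([[10, 0, 90], [5, 5, 0], [0, 0, 0], [1, 2, 3]]))
    return CellByFeatureMatrix(["c1", "c2", "c3", "c4"], ["f1", "f2", "f3"], X)


def make_fragments(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
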