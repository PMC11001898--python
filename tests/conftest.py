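import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import lungspan as ls
from lungspan.containers import CellAnnotation, CountMatrix, NormalizedMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic dataset, shared read-only across tests."""
    cfg = ls.SimulationConfig(
        n_genes=800,
        cells_per_group={g: 100 for g in ls.GROUPS},
        seed=42,
    )
    return ls.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    counts, ann, truth = small_dataset
    counts, ann, _ = ls.qc_filter(counts, ann)
    return ls.normalize(counts), ann, truth


@pytest.fixture()
def toy_counts():
    """2 genes x 3 cells hand-checkable matrix."""
    counts = sp.csr_matrix(np.array([[1, 0, 7], [2, 3, 0]]))
    cm = CountMatrix(["GA", "GB"], ["c1", "c2", "c3"], counts)
    meta = pd.DataFrame({
        "cell": ["c1", "c2", "c3"],
        "sample": ["s1", "s1", "s2"],
        "group": ["T1", "T1", "T5"],
        "cell_type": ["AT2", "AT2", "AT2"],
    })
    ann = CellAnnotation.from_frame(meta, cm)
    return cm, ann


def make_norm(values, genes=None, cells=None, groups=None, cell_types=None):
    """NormalizedMatrix + matching annotation straight from an array."""
    values = np.asarray(values, dtype=float)
    n_g, n_c = values.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    cells = cells or [f"c{i}" for i in range(n_c)]
    norm = NormalizedMatrix(genes, cells, values)
    meta = pd.DataFrame({
        "cell": cells,
        "sample": "s1",
        "group": groups or ["T1"] * n_c,
        "cell_type": cell_types or ["AT2"] * n_c,
        "n_feature": (values > 0).sum(axis=0),
        "percent_mt": 0.0,
    })
    ann = CellAnnotation.from_frame(meta)
    return norm, ann
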