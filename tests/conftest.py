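import numpy as np
import pandas as pd
import pytest

from pepregnet.io import ExpressionMatrix, load_panel


@pytest.fixture(scope="session")
def panel():
    return load_panel()


def make_matrix(counts, gene_ids=None, tissue=None, annotation=None,
                age_days=None, sex=None):
    """Build an ExpressionMatrix from a raw count array with default metadata."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = np.array([f"c{i}" for i in range(n_cells)])
    if gene_ids is None:
        gene_ids = np.array([f"g{j}" for j in range(n_genes)])
    meta = pd.DataFrame(
        {
            "tissue": tissue if tissue is not None else ["head"] * n_cells,
            "annotation": annotation if annotation is not None else ["head_other"] * n_cells,
            "age_days": age_days if age_days is not None else [5] * n_cells,
            "sex": sex if sex is not None else ["male"] * n_cells,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return ExpressionMatrix(cell_ids=cell_ids, gene_ids=np.asarray(gene_ids, dtype=str),
                            counts=counts, cell_meta=meta)


@pytest.fixture
def matrix_factory():
    return make_matrix
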