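import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sclandscape.io import AnnotatedCounts
from sclandscape.preprocess import NormalizedMatrix, lognormalize


def make_counts(matrix, gene_ids=None, cell_ids=None, groups=None, clusters=None,
                patients=None, layers=None):
    """Build an AnnotatedCounts from a dense array with minimal metadata."""
    matrix = np.asarray(matrix)
    g, c = matrix.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    cell_ids = cell_ids or [f"c{i}" for i in range(c)]
    meta = pd.DataFrame(
        {
            "patient": patients or ["P1"] * c,
            "group": groups or ["WT"] * c,
            "cluster": clusters or ["C0"] * c,
        },
        index=cell_ids,
    )
    return AnnotatedCounts(sp.csc_matrix(matrix), gene_ids, cell_ids, meta,
                           layers=layers or {})


def norm_from_values(values, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    """NormalizedMatrix with the given (already log-scale) values."""
    values = np.asarray(values, float)
    g, c = values.shape
    return NormalizedMatrix(
        sp.csc_matrix(values), 10_000.0,
        gene_ids or [f"g{i}" for i in range(g)],
        cell_ids or [f"c{i}" for i in range(c)],
    )


@pytest.fixture
def toy_counts():
    """3 genes x 4 cells, two groups, two clusters."""
    return make_counts(
        [[5, 0, 2, 1], [0, 3, 0, 4], [1, 1, 1, 1]],
        groups=["WT", "WT", "MT", "MT"],
        clusters=["C0", "C1", "C0", "C1"],
        patients=["P1", "P1", "P2", "P2"],
    )


@pytest.fixture(scope="session")
def pipeline_dataset(tmp_path_factory):
    """A small full synthetic dataset shared by pipeline-level tests."""
    from sclandscape.scenario import simulate_dataset

    scn = {
        "group_totals": {"WT": 700, "MT": 700},
        "n_genes": 200,
        "bulk": {"n_samples": 30, "designated_subset": "C2",
                 "noise_sd": 0.05, "slope": 25.0, "intercept": -5.0},
    }
    out = tmp_path_factory.mktemp("dataset")
    return simulate_dataset(scn, seed=7, out_dir=out)
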