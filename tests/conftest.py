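import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import rloopsc as r
from rloopsc.simulate import gene_coordinates


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared across read-only tests."""
    cfg = r.SimConfig(
        n_cells=600,
        seed=11,
        lr_pairs_planted=[("G0500", "G0510", "Epithelial", "Type2")],
    )
    matrix, truth = r.generate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def normalized_sim(small_sim):
    cfg, matrix, truth = small_sim
    f = r.scale_genes(r.lognormalize(r.qc_filter(matrix)))
    return cfg, f, truth


@pytest.fixture(scope="session")
def sim_coords(normalized_sim):
    _, f, _ = normalized_sim
    return gene_coordinates(f.gene_names)


@pytest.fixture()
def tiny_matrix():
    """4 genes x 3 cells toy with a normalized layer, handy for oracles."""
    counts = np.array([[1, 0, 2, 4], [0, 3, 1, 2], [5, 1, 0, 1]])
    m = r.CountMatrix(
        sp.csr_matrix(counts),
        pd.Index(["gA", "gB", "gC", "gD"]),
        pd.Index(["c1", "c2", "c3"]),
        None,
    )
    return r.lognormalize(m)
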