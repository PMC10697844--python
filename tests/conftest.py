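"""Shared fixtures: handcrafted toy matrices and session-scoped synthetic data.

The heavy synthetic fixtures (atlas + markers, two-species pair, paralog
panel) are session-scoped so the marker detection and summaries are
computed once and shared between the unit and acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scevolink import core_model as cm
from scevolink import specificity as spc
from scevolink import synthetic_data as syn

FIXTURE_SEED = 7


def make_cell_matrix(counts, gene_ids=None, cell_ids=None, cluster=None,
                     sample=None, sex=None, mito=()):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample": sample if sample is not None else ["s1"] * n_cells,
            "sex": sex if sex is not None else ["unknown"] * n_cells,
            "cluster": cluster if cluster is not None else [pd.NA] * n_cells,
        },
        index=cell_ids,
    )
    return cm.CellMatrix(sp.csr_matrix(counts), np.array(gene_ids, dtype=object),
                         np.array(cell_ids, dtype=object), meta, frozenset(mito))


@pytest.fixture
def tiny_matrix():
    """4 genes x 6 cells, two clusters, one mito gene."""
    counts = np.array(
        [
            [5, 0, 3, 0, 1, 2],
            [0, 7, 0, 2, 0, 0],
            [1, 1, 1, 1, 1, 1],
            [2, 0, 0, 4, 0, 1],
        ]
    )
    return make_cell_matrix(
        counts,
        gene_ids=["MT-a", "gb", "gc", "gd"],
        cluster=["k1", "k1", "k1", "k2", "k2", "k2"],
        mito=["MT-a"],
    )


@pytest.fixture(scope="session")
def sim_cfg():
    return syn.SimConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def atlas(sim_cfg):
    return syn.simulate_cell_matrix(sim_cfg)


@pytest.fixture(scope="session")
def atlas_norm(atlas):
    matrix, _ = atlas
    qc = cm.apply_qc_filters(matrix)
    return qc, cm.log_normalize(qc)


@pytest.fixture(scope="session")
def atlas_markers(atlas_norm):
    qc, nm = atlas_norm
    return spc.find_markers(nm, qc.cell_meta["cluster"])


@pytest.fixture(scope="session")
def atlas_summary(atlas_norm):
    qc, nm = atlas_norm
    return cm.summarize_clusters(nm, qc)


@pytest.fixture(scope="session")
def paralog_panel(sim_cfg):
    return syn.simulate_paralog_expression(sim_cfg)


@pytest.fixture(scope="session")
def two_species(sim_cfg):
    return syn.simulate_two_species(sim_cfg)


@pytest.fixture(scope="session")
def two_species_markers(two_species):
    m_a, m_b, om, truth = two_species
    nm_a, nm_b = cm.log_normalize(m_a), cm.log_normalize(m_b)
    mk_a = spc.find_markers(nm_a, m_a.cell_meta["cluster"])
    mk_b = spc.find_markers(nm_b, m_b.cell_meta["cluster"])
    cs_a = cm.summarize_clusters(nm_a, m_a)
    cs_b = cm.summarize_clusters(nm_b, m_b)
    return mk_a, mk_b, cs_a, cs_b
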