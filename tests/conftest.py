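import numpy as np
import pytest
from scipy import sparse

from islet_identity import (CountMatrix, PopulationConfig, default_panel,
                            identity_table, normalize, score_cells,
                            simulate_counts)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_panel():
    """Default signatures with only 20 background genes — fast to simulate."""
    return default_panel(n_background=20)


def run_identity(panel, config):
    """Simulate -> normalize -> score -> identity table, truth-anchored."""
    cm, truth = simulate_counts(panel, config)
    nm = normalize(cm)
    scores = score_cells(nm, {"beta": panel.beta_genes,
                              "alpha": panel.alpha_genes})
    tmap = truth.set_index("cell_id")["true_type"].reindex(cm.cell_ids)
    beta_ref = (tmap == "beta").to_numpy()
    alpha_ref = (tmap == "alpha").to_numpy()
    table, b_stats, a_stats = identity_table(
        cm.cell_ids, scores["score_alpha"].to_numpy(),
        scores["score_beta"].to_numpy(), beta_ref, alpha_ref)
    return dict(counts=cm, truth=truth, normalized=nm, scores=scores,
                table=table, beta_stats=b_stats, alpha_stats=a_stats)


@pytest.fixture(scope="session")
def default_run(small_panel):
    """One full scoring run on the default population layout (seed 1)."""
    return run_identity(small_panel, PopulationConfig(seed=1))


def toy_counts(array, gene_ids=None, cell_ids=None):
    array = np.asarray(array)
    g, c = array.shape
    return CountMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        cell_ids=cell_ids or [f"c{i}" for i in range(c)],
        counts=sparse.csr_matrix(array))
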