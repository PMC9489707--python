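import numpy as np
import pytest

from ecatlas import qc
from ecatlas import syndata as sd


@pytest.fixture(scope="session")
def small_sim():
    """4 well-separated planted clusters, 80 cells each."""
    cfg = sd.SimConfig(
        n_genes=1000, n_clusters=4, n_cells_per_cluster=[80] * 4, seed=11
    )
    return sd.simulate_counts(cfg)


@pytest.fixture(scope="session")
def small_nm(small_sim):
    adata, truth = small_sim
    adata2 = qc.filter_genes(adata)
    adata3, _ = qc.filter_cells(adata2)
    nm = qc.normalize_scale(adata3)
    labels = truth.true_labels.loc[nm.obs_names]
    return nm, labels, truth


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook step-up Benjamini-Hochberg, quadratic and explicit."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj
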