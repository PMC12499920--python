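import numpy as np
import pytest

from stardust import StardustConfig, run_stardust, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """300 cells, 5 well-separated planted clusters; quick pipeline food."""
    counts, truth = simulate_counts(
        n_cells=300, n_genes=600, n_clusters=5, markers_per_cluster=30,
        log2fc=2.0, nb_dispersion=0.3, seed=7)
    return counts, truth


@pytest.fixture(scope="session")
def small_run(small_sim):
    counts, truth = small_sim
    cfg = StardustConfig(seed=1, sps=False, n_top_hvgs=300, pca_components=50)
    return run_stardust(counts, cfg), counts, truth


@pytest.fixture(scope="session")
def standard_sim():
    """The standard synthetic fixture: 1000 cells, 2000 genes, 5 clusters,
    50 markers per cluster, log2fc 2, NB dispersion 0.3, seed 7."""
    counts, truth = simulate_counts(
        n_cells=1000, n_genes=2000, n_clusters=5, markers_per_cluster=50,
        log2fc=2.0, nb_dispersion=0.3, seed=7)
    return counts, truth


@pytest.fixture(scope="session")
def standard_run(standard_sim):
    counts, truth = standard_sim
    cfg = StardustConfig(seed=1, sps=False)
    return run_stardust(counts, cfg), counts, truth


def truth_aligned(result, counts, truth):
    """Planted labels reordered to the result's cell order."""
    lookup = dict(zip(counts.cell_ids, truth.labels))
    return np.array([lookup[c] for c in result.labels.cell_ids])
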