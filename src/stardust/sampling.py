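"""Structure-preserving subsampling (SPS).

Large datasets are thinned before layout, but uniform subsampling would
erode rare populations.  SPS first clusters a quick cell kNN graph, then
samples each preliminary cluster at a proportion that decays exponentially
with cluster size,

    p_i = p_l - exp(-s_i / k) * (p_l - p_u),

so a tiny cluster is kept at close to the upper bound ``p_u`` while a huge
one is thinned down toward the lower bound ``p_l``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = ["SamplingPlan", "sps_proportion", "sps_subsample", "preliminary_clusters"]

#: datasets at or below this many cells skip subsampling entirely
SPS_SKIP_THRESHOLD = 5000


@dataclass
class SamplingPlan:
    cluster_sizes: np.ndarray
    proportions: np.ndarray
    sampled_cell_ids: np.ndarray
    p_l: float
    p_u: float
    k_scale: float
    seed: int

    def leftover(self, all_cell_ids) -> np.ndarray:
        sampled = set(self.sampled_cell_ids)
        return np.array([c for c in all_cell_ids if c not in sampled], dtype=str)


def sps_proportion(s, p_l: float, p_u: float, k_scale: float):
    """Sampling proportion for a cluster of size ``s`` (vectorized over s)."""
    if not (0 < p_l <= 1 and 0 < p_u <= 1):
        raise ValueError("p_l and p_u must lie in (0, 1]")
    if k_scale <= 0:
        raise ValueError("k_scale must be positive")
    s = np.asarray(s, dtype=float)
    return p_l - np.exp(-s / k_scale) * (p_l - p_u)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def preliminary_clusters(norm: NormalizedMatrix, seed: int = 0,
                         n_comp: int = 50, k: int = 20) -> np.ndarray:
    """Quick kNN-graph community detection used only to drive sampling.

    Modularity (Leiden) communities on the PCA kNN graph; deterministic for
    a given seed.
    """
    import igraph as ig
    import leidenalg

    from .network import build_cell_edges, compute_pca

    pca = compute_pca(norm, n_comp=min(n_comp, norm.n_cells - 1, norm.n_genes),
                      seed=seed)
    pairs = build_cell_edges(pca, k=min(k, norm.n_cells - 1), seed=seed)
    uniq = {(min(a, b), max(a, b)) for a, b in pairs}
    g = ig.Graph(n=norm.n_cells, edges=sorted(uniq))
    part = leidenalg.find_partition(g, leidenalg.ModularityVertexPartition,
                                    seed=seed)
    return np.asarray(part.membership, dtype=int)


def sps_subsample(norm: NormalizedMatrix, seed: int = 0, p_l: float = 0.3,
                  p_u: float = 0.9, k_scale: float = 500.0,
                  clusters: np.ndarray | None = None) -> SamplingPlan:
    """Sample each preliminary cluster at its decay-function proportion.

    Per-cluster sample counts are round-half-away-from-zero of p_i * s_i,
    floored at one cell, drawn without replacement with the given seed.
    ``clusters`` may supply a precomputed preliminary labeling.
    """
    if norm.n_cells < 2:
        raise ValueError("subsampling requires at least 2 cells")
    if clusters is None:
        clusters = preliminary_clusters(norm, seed=seed)
    clusters = np.asarray(clusters, dtype=int)
    rng = np.random.default_rng(seed)

    cluster_ids = np.unique(clusters)
    sizes = np.array([(clusters == c).sum() for c in cluster_ids])
    props = sps_proportion(sizes, p_l, p_u, k_scale)
    sampled: list[str] = []
    for c, s, p in zip(cluster_ids, sizes, props):
        take = max(1, _round_half_away(p * s))
        members = norm.cell_ids[clusters == c]
        chosen = rng.choice(members, size=min(take, s), replace=False)
        sampled.extend(chosen)
    order = {c: i for i, c in enumerate(norm.cell_ids)}
    sampled_ids = np.array(sorted(sampled, key=order.__getitem__), dtype=str)
    log.info("SPS: kept %d of %d cells across %d preliminary clusters",
             sampled_ids.size, norm.n_cells, cluster_ids.size)
    return SamplingPlan(
        cluster_sizes=sizes, proportions=np.asarray(props, dtype=float),
        sampled_cell_ids=sampled_ids, p_l=p_l, p_u=p_u, k_scale=k_scale, seed=seed,
    )
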