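"""Density-based clustering of the layout, and post-hoc label transfer.

Cells are clustered with DBSCAN on their 2D layout coordinates; cells held
out by subsampling are assigned afterwards by majority vote among their k
nearest sampled cells in PC space, with coordinates set to the mean of the
same-cluster neighbors.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import NOISE_LABEL, ClusterAssignment, Embedding2D
from .network import PCAEmbedding

log = logging.getLogger(__name__)

__all__ = ["estimate_eps", "dbscan_embed", "posthoc_assign"]


def estimate_eps(coords: np.ndarray, k: int = 20) -> float:
    """Knee of the sorted k-distance curve (max distance to the chord).

    The standard DBSCAN calibration: sort every point's distance to its
    k-th neighbor and take the curve point farthest from the straight line
    joining the endpoints.  Force-directed layouts can collapse tight
    groups onto (near-)coincident positions, which puts a flat zero
    segment at the front of the curve and drags the naive knee to zero;
    the knee is therefore computed on the positive segment only and
    floored at 1.2x the median k-distance.
    """
    from sklearn.neighbors import NearestNeighbors

    n = coords.shape[0]
    k = min(k, n - 1)
    dist, _ = NearestNeighbors(n_neighbors=k + 1).fit(coords).kneighbors(coords)
    kdist = np.sort(dist[:, -1])
    pos = kdist[kdist > 1e-12]
    if pos.size == 0:
        return 1e-6
    m = pos.size
    x = np.arange(m, dtype=float)
    chord = np.array([max(m - 1, 1), pos[-1] - pos[0]])
    chord = chord / np.linalg.norm(chord)
    rel = np.column_stack([x, pos - pos[0]])
    # perpendicular distance to the chord
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    knee = float(pos[int(np.argmax(perp))])
    return float(max(knee, 1.2 * np.median(kdist), 1e-6))


def dbscan_embed(emb: Embedding2D, eps: float | None = None,
                 min_samples: int = 20) -> ClusterAssignment:
    """DBSCAN on the cell coordinates of a layout.

    ``eps`` defaults to the k-distance knee with k = min_samples.  Noise
    points get the -1 sentinel; non-noise labels are relabeled to 0..K-1.
    """
    from sklearn.cluster import DBSCAN

    cells = emb.restrict("cell") if "gene" in emb.node_types else emb
    coords = cells.coords
    if coords.shape[0] < min_samples:
        raise ValueError(f"need at least min_samples={min_samples} cells")
    if eps is None:
        eps = estimate_eps(coords, k=min_samples)
        log.info("dbscan_embed: knee-estimated eps = %.4f", eps)
    if eps <= 0:
        raise ValueError("eps must be positive")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)
    out = ClusterAssignment(cells.node_ids, labels,
                            np.array(["dbscan"] * coords.shape[0]))
    return out.relabel_contiguous()


def posthoc_assign(leftover_cells, pca: PCAEmbedding,
                   sampled_labels: ClusterAssignment,
                   sampled_coords: Embedding2D,
                   k: int = 20) -> tuple[ClusterAssignment, Embedding2D]:
    """Assign held-out cells to existing clusters via kNN majority vote.

    Neighbors are searched in PC space among the sampled cells.  Ties are
    broken by the cluster of the single nearest neighbor.  Each assigned
    cell is placed at the mean 2D position of those of its neighbors that
    carry the assigned label; if the assigned label is the noise sentinel,
    the mean over all neighbors is used.
    """
    from sklearn.neighbors import NearestNeighbors

    leftover_cells = np.asarray(leftover_cells, dtype=str)
    if leftover_cells.size == 0:
        return (ClusterAssignment(leftover_cells, np.empty(0, dtype=int),
                                  np.empty(0, dtype=str)),
                Embedding2D(leftover_cells, np.empty(0, dtype=str),
                            np.empty((0, 2))))
    if set(leftover_cells) & set(sampled_labels.cell_ids):
        raise ValueError("leftover and sampled cell sets overlap")
    n_sampled = sampled_labels.cell_ids.size
    if k > n_sampled:
        log.warning("posthoc_assign: clamping k from %d to %d sampled cells",
                    k, n_sampled)
        k = n_sampled

    pos = {c: i for i, c in enumerate(pca.cell_ids)}
    sampled_idx = np.array([pos[c] for c in sampled_labels.cell_ids])
    left_idx = np.array([pos[c] for c in leftover_cells])
    nn = NearestNeighbors(n_neighbors=k).fit(pca.scores[sampled_idx])
    _, nbr = nn.kneighbors(pca.scores[left_idx])

    coords2d = sampled_coords.lookup(sampled_labels.cell_ids)
    out_labels = np.empty(leftover_cells.size, dtype=int)
    out_coords = np.empty((leftover_cells.size, 2))
    for i, row in enumerate(nbr):
        votes = sampled_labels.labels[row]
        vals, counts = np.unique(votes, return_counts=True)
        winners = vals[counts == counts.max()]
        label = int(winners[0]) if winners.size == 1 else int(votes[0])
        out_labels[i] = label
        mask = votes == label
        sel = row[mask] if mask.any() else row
        out_coords[i] = coords2d[sel].mean(axis=0)
    assign = ClusterAssignment(leftover_cells, out_labels,
                               np.array(["posthoc"] * leftover_cells.size))
    emb = Embedding2D(leftover_cells, np.array(["cell"] * leftover_cells.size),
                      out_coords, seed=sampled_coords.seed,
                      edge_cut=sampled_coords.edge_cut)
    return assign, emb
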