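"""Construction of the cell-gene nearest-neighbor network (CGNNN).

Cell-cell edges come from kNN in PCA space (exact search below a size
threshold, an approximate NN-descent index above it).  Cell-gene edges
connect each selected gene to the cells where its normalized expression is
highest; in the final pass the number of cells per gene decays with the
gene's within-cluster marker rank, p = 5 - ceil(i/10), so higher-quality
markers anchor to more cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CellGeneGraph,
    ClusterAssignment,
    GeneSelection,
    NormalizedMatrix,
)

log = logging.getLogger(__name__)

__all__ = [
    "PCAEmbedding",
    "compute_pca",
    "pca_gene_selection",
    "build_cell_edges",
    "build_gene_edges",
    "build_gene_edges_pass4",
    "build_cgnnn",
    "write_graphml",
    "read_graphml",
    "write_edge_list",
    "read_edge_list",
]

#: below this many cells, kNN search is exact brute force
EXACT_NN_THRESHOLD = 2000
#: below this many cells, PCA uses the full (deterministic) SVD solver
EXACT_PCA_THRESHOLD = 5000


@dataclass
class PCAEmbedding:
    scores: np.ndarray          # (n_cells, n_comp)
    loadings: np.ndarray        # (n_genes, n_comp), unit-norm columns
    explained_variance: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    @property
    def n_comp(self) -> int:
        return self.scores.shape[1]


def compute_pca(norm: NormalizedMatrix, n_comp: int = 500, seed: int = 0) -> PCAEmbedding:
    """Centered PCA of the normalized log matrix.

    ``n_comp`` is clamped to min(requested, cells - 1, genes).  The full
    SVD solver is used below ``EXACT_PCA_THRESHOLD`` cells; above it a
    seeded randomized solver keeps runtime bounded.
    """
    from sklearn.decomposition import PCA

    if norm.n_cells < 2:
        raise ValueError("PCA requires at least 2 cells")
    if not np.any(norm.values.std(axis=0) > 0):
        raise ValueError("degenerate matrix: zero variance in every gene")
    limit = min(norm.n_cells - 1, norm.n_genes)
    if n_comp > limit:
        log.info("compute_pca: clamping n_comp from %d to %d", n_comp, limit)
        n_comp = limit
    solver = "full" if norm.n_cells <= EXACT_PCA_THRESHOLD else "randomized"
    pca = PCA(n_components=n_comp, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(norm.values)
    return PCAEmbedding(
        scores=scores,
        loadings=pca.components_.T.copy(),
        explained_variance=pca.explained_variance_.copy(),
        cell_ids=norm.cell_ids,
        gene_ids=norm.gene_ids,
    )


def pca_gene_selection(pca: PCAEmbedding, n_genes: int = 500) -> GeneSelection:
    """Rank genes by their maximum absolute loading over the components."""
    n_genes = min(n_genes, pca.gene_ids.size)
    score = np.abs(pca.loadings).max(axis=1)
    order = np.argsort(-score, kind="stable")[:n_genes]
    return GeneSelection(pca.gene_ids[order], "pca_loading", score[order])


def build_cell_edges(pca: PCAEmbedding, k: int = 20, exact: bool | None = None,
                     seed: int = 0) -> np.ndarray:
    """Undirected unit edges joining each cell to its k nearest cells.

    Euclidean distance in PC space.  Directed kNN lists are symmetrized by
    union (mutuality is not required).  Returns an (m, 2) array of cell
    index pairs.
    """
    n = pca.scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    if exact is None:
        exact = n <= EXACT_NN_THRESHOLD
    if exact:
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(pca.scores)
        _, idx = nn.kneighbors(pca.scores)
        neighbors = idx[:, 1:]
    else:
        import pynndescent

        index = pynndescent.NNDescent(pca.scores, n_neighbors=k + 1,
                                      metric="euclidean", random_state=seed)
        idx, _ = index.neighbor_graph
        # drop self matches; NN-descent usually puts self first but not always
        neighbors = np.empty((n, k), dtype=int)
        for i in range(n):
            row = idx[i][idx[i] != i][:k]
            if row.size < k:  # pad from remaining candidates
                row = np.concatenate([row, idx[i][: k - row.size]])
            neighbors[i] = row
    src = np.repeat(np.arange(n), k)
    pairs = np.column_stack([src, neighbors.ravel()])
    return pairs


def build_gene_edges(norm: NormalizedMatrix, genes: GeneSelection,
                     n: int = 10) -> np.ndarray:
    """Connect each selected gene to its top-n cells by normalized expression.

    Ties are broken by cell order in the matrix (stable argsort), which makes
    the construction deterministic.  Returns (m, 2) pairs of
    (cell_index, gene_position) where gene_position indexes ``genes``.
    """
    cols = norm.gene_index(genes.gene_ids)
    n_eff = min(n, norm.n_cells)
    pairs = []
    for pos, col in enumerate(cols):
        top = np.argsort(-norm.values[:, col], kind="stable")[:n_eff]
        pairs.extend((int(c), pos) for c in top)
    return np.array(pairs, dtype=int).reshape(-1, 2)


def pass4_edge_count(rank: int) -> int:
    """Cells per gene in the final pass: p = 5 - ceil(rank/10)."""
    if rank < 1:
        raise ValueError("ranks are 1-based")
    return 5 - math.ceil(rank / 10)


def build_gene_edges_pass4(markers: pd.DataFrame, labels: ClusterAssignment,
                           norm: NormalizedMatrix,
                           gene_order: np.ndarray) -> np.ndarray:
    """Final-pass gene edges: rank-i markers join p = 5 - ceil(i/10) cells.

    The p cells are the top-p by the gene's normalized expression among the
    cells of the marker's own cluster.  ``gene_order`` fixes the gene-node
    indexing of the pass-4 graph.
    """
    gene_pos = {g: i for i, g in enumerate(gene_order)}
    cell_pos = {c: i for i, c in enumerate(norm.cell_ids)}
    pairs = []
    for _, row in markers.iterrows():
        gene, cluster, rank = row["gene_id"], row["cluster"], int(row["rank_in_cluster"])
        p = pass4_edge_count(rank)
        members = [cell_pos[c] for c in labels.members(cluster) if c in cell_pos]
        if not members:
            continue
        if len(members) < p:
            log.warning("cluster %s has %d < %d cells; connecting gene %s to all",
                        cluster, len(members), p, gene)
        members = np.asarray(members)
        col = norm.gene_index([gene])[0]
        expr = norm.values[members, col]
        top = members[np.argsort(-expr, kind="stable")[:p]]
        pairs.extend((int(c), gene_pos[gene]) for c in top)
    return np.array(pairs, dtype=int).reshape(-1, 2)


def build_cgnnn(norm: NormalizedMatrix, pca: PCAEmbedding, genes: GeneSelection,
                k: int = 20, n: int = 10, exact: bool | None = None,
                seed: int = 0) -> CellGeneGraph:
    """Assemble the full pass-1-to-3 CGNNN from its two edge classes."""
    graph = CellGeneGraph(norm.cell_ids, genes.gene_ids)
    graph.add_cell_cell_edges(build_cell_edges(pca, k=k, exact=exact, seed=seed))
    graph.add_cell_gene_edges(build_gene_edges(norm, genes, n=n))
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def write_graphml(graph: CellGeneGraph, path) -> None:
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))


def read_graphml(path) -> CellGeneGraph:
    import networkx as nx

    g = nx.read_graphml(str(path))
    cells = sorted(n for n, d in g.nodes(data=True) if d.get("node_type") == "cell")
    genes = sorted(n for n, d in g.nodes(data=True) if d.get("node_type") == "gene")
    return _graph_from_parts(cells, genes, g.edges())


def write_edge_list(graph: CellGeneGraph, edges_path, types_path) -> None:
    """Two-column edge list plus a node_id/node_type sidecar table."""
    ids = graph.node_ids
    pd.DataFrame(
        [(ids[a], ids[b]) for a, b in graph.edge_array()], columns=["source", "target"]
    ).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame({"node_id": graph.node_ids, "node_type": graph.node_types}).to_csv(
        types_path, sep="\t", index=False)


def read_edge_list(edges_path, types_path) -> CellGeneGraph:
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    types = pd.read_csv(types_path, sep="\t", dtype=str)
    cells = types.loc[types["node_type"] == "cell", "node_id"].tolist()
    genes = types.loc[types["node_type"] == "gene", "node_id"].tolist()
    return _graph_from_parts(cells, genes, edges.itertuples(index=False))


def _graph_from_parts(cells, genes, edge_iter) -> CellGeneGraph:
    graph = CellGeneGraph(cells, genes)
    cell_pos = {c: i for i, c in enumerate(graph.cell_ids)}
    gene_pos = {g: i for i, g in enumerate(graph.gene_ids)}
    cc, cg = [], []
    for a, b in edge_iter:
        if a in cell_pos and b in cell_pos:
            cc.append((cell_pos[a], cell_pos[b]))
        elif a in cell_pos and b in gene_pos:
            cg.append((cell_pos[a], gene_pos[b]))
        elif b in cell_pos and a in gene_pos:
            cg.append((cell_pos[b], gene_pos[a]))
        else:
            raise ValueError(f"illegal gene-gene edge {a}--{b}")
    if cc:
        graph.add_cell_cell_edges(cc)
    if cg:
        graph.add_cell_gene_edges(cg)
    graph.validate()
    return graph
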