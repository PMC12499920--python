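"""Core in-memory containers shared across the pipeline.

The containers are deliberately thin: matrices are numpy arrays (or scipy
sparse matrices for raw counts) with string identifiers, graphs store typed
index-pair edge arrays, and tabular results are pandas DataFrames with a
documented column contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneSelection",
    "CellGeneGraph",
    "Embedding2D",
    "ClusterAssignment",
    "MARKER_COLUMNS",
    "validate_marker_table",
]


def _as_str_array(ids) -> np.ndarray:
    arr = np.asarray(ids, dtype=str)
    if arr.ndim != 1:
        raise ValueError("identifier list must be one-dimensional")
    if len(np.unique(arr)) != arr.size:
        raise ValueError("duplicate identifiers are not allowed")
    return arr


@dataclass
class CountMatrix:
    """Raw UMI counts, cells as rows.

    ``values`` is a dense ndarray or a scipy sparse matrix of shape
    (n_cells, n_genes) holding non-negative integers.
    """

    values: object
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.values.shape != (self.cell_ids.size, self.gene_ids.size):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{self.cell_ids.size} cells x {self.gene_ids.size} genes"
            )
        data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
        if data.size and (not np.all(np.isfinite(data)) or np.any(data < 0)):
            raise ValueError("counts must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        values, cells, genes = self.values, self.cell_ids, self.gene_ids
        if cell_mask is not None:
            values = values[cell_mask]
            cells = cells[cell_mask]
        if gene_mask is not None:
            values = values[:, gene_mask]
            genes = genes[gene_mask]
        return CountMatrix(values, cells, genes)


@dataclass
class NormalizedMatrix:
    """log1p of median-scaled counts; always dense float64."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    median_total: float

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.cell_ids.size, self.gene_ids.size):
            raise ValueError("matrix shape does not match identifiers")
        if self.median_total <= 0:
            raise ValueError("median_total must be positive")
        if self.values.size and self.values.min() < 0:
            raise ValueError("log1p-normalized values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present in matrix") from exc

    def cell_index(self, cell_ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"cell {exc.args[0]!r} not present in matrix") from exc


@dataclass
class GeneSelection:
    """An ordered gene subset with the per-gene score that ranked it."""

    gene_ids: np.ndarray
    method: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != self.gene_ids.shape:
            raise ValueError("one score per gene required")
        if self.method not in {"hvg_dispersion", "pca_loading", "de"}:
            raise ValueError(f"unknown selection method {self.method!r}")

    def __len__(self) -> int:
        return self.gene_ids.size


class CellGeneGraph:
    """Heterogeneous cell-gene graph with unit-weight edges.

    Only two edge classes are legal: cell-cell and cell-gene.  Gene-gene
    edges cannot be represented and any attempt to add one fails.  Nodes are
    ordered cells first, then genes, which fixes the layout node order.
    """

    def __init__(self, cell_ids, gene_ids) -> None:
        self.cell_ids = _as_str_array(cell_ids)
        self.gene_ids = _as_str_array(gene_ids) if len(gene_ids) else np.array([], dtype=str)
        overlap = set(self.cell_ids) & set(self.gene_ids)
        if overlap:
            raise ValueError(f"identifiers used for both cells and genes: {sorted(overlap)[:5]}")
        self._cc: set[tuple[int, int]] = set()
        self._cg: set[tuple[int, int]] = set()

    # -- construction -----------------------------------------------------
    def add_cell_cell_edges(self, pairs) -> None:
        for a, b in np.asarray(pairs, dtype=int).reshape(-1, 2):
            if a == b:
                continue
            self._cc.add((min(a, b), max(a, b)))

    def add_cell_gene_edges(self, pairs) -> None:
        """``pairs`` holds (cell_index, gene_index) tuples."""
        n_c, n_g = self.n_cells, self.n_genes
        for c, g in np.asarray(pairs, dtype=int).reshape(-1, 2):
            if not (0 <= c < n_c and 0 <= g < n_g):
                raise IndexError(f"cell-gene edge ({c},{g}) out of range")
            self._cg.add((int(c), int(g)))

    # -- views ------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_nodes(self) -> int:
        return self.n_cells + self.n_genes

    @property
    def node_ids(self) -> np.ndarray:
        return np.concatenate([self.cell_ids, self.gene_ids])

    @property
    def node_types(self) -> np.ndarray:
        return np.array(["cell"] * self.n_cells + ["gene"] * self.n_genes)

    def cell_cell_edges(self) -> np.ndarray:
        if not self._cc:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self._cc), dtype=int)

    def cell_gene_edges(self) -> np.ndarray:
        if not self._cg:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self._cg), dtype=int)

    def edge_array(self) -> np.ndarray:
        """All edges in unified node indexing (genes offset by n_cells)."""
        cc = self.cell_cell_edges()
        cg = self.cell_gene_edges()
        if cg.size:
            cg = np.column_stack([cg[:, 0], cg[:, 1] + self.n_cells])
        return np.vstack([cc, cg]) if cc.size or cg.size else np.empty((0, 2), dtype=int)

    @property
    def n_edges(self) -> int:
        return len(self._cc) + len(self._cg)

    def gene_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=int)
        for _, g in self._cg:
            deg[g] += 1
        return deg

    def validate(self) -> None:
        """Assert the structural invariants (edge classes, no loops)."""
        n_c = self.n_cells
        for a, b in self._cc:
            if a == b:
                raise ValueError("self-loop in cell-cell edges")
            if not (0 <= a < n_c and 0 <= b < n_c):
                raise ValueError("cell-cell edge touches a gene node")
        for c, g in self._cg:
            if not (0 <= c < n_c and 0 <= g < self.n_genes):
                raise ValueError("cell-gene edge index out of range")
        if self.n_nodes == 0:
            raise ValueError("empty graph")

    # -- interchange ------------------------------------------------------
    def to_igraph(self):
        import igraph as ig

        g = ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edge_array()])
        g.vs["name"] = list(self.node_ids)
        g.vs["node_type"] = list(self.node_types)
        g.es["weight"] = 1.0
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for nid, ntype in zip(self.node_ids, self.node_types):
            g.add_node(str(nid), node_type=str(ntype))
        ids = self.node_ids
        for a, b in self.edge_array():
            g.add_edge(str(ids[a]), str(ids[b]), weight=1.0)
        return g


@dataclass
class Embedding2D:
    """Per-node 2D coordinates, for cells and genes alike."""

    node_ids: np.ndarray
    node_types: np.ndarray
    coords: np.ndarray
    seed: int | None = None
    edge_cut: float = 0.8

    def __post_init__(self) -> None:
        self.node_ids = _as_str_array(self.node_ids)
        self.node_types = np.asarray(self.node_types, dtype=str)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (self.node_ids.size, 2):
            raise ValueError("coords must be (n_nodes, 2)")
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def restrict(self, node_type: str) -> "Embedding2D":
        mask = self.node_types == node_type
        return Embedding2D(
            self.node_ids[mask], self.node_types[mask], self.coords[mask],
            seed=self.seed, edge_cut=self.edge_cut,
        )

    def lookup(self, node_ids) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.node_ids)}
        missing = [n for n in node_ids if n not in pos]
        if missing:
            raise KeyError(f"nodes missing from embedding: {missing[:10]}")
        return self.coords[[pos[n] for n in node_ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "node_type": self.node_types,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
            }
        )


NOISE_LABEL = -1


@dataclass
class ClusterAssignment:
    """Per-cell integer labels; -1 marks noise / unassigned cells."""

    cell_ids: np.ndarray
    labels: np.ndarray
    source: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.cell_ids.shape:
            raise ValueError("one label per cell required")
        if self.source is None:
            self.source = np.array(["dbscan"] * self.cell_ids.size)
        else:
            self.source = np.asarray(self.source, dtype=str)

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels[self.labels >= 0]).size)

    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels >= 0])

    def members(self, cluster: int) -> np.ndarray:
        return self.cell_ids[self.labels == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "cluster": self.labels, "source": self.source}
        )

    def relabel_contiguous(self) -> "ClusterAssignment":
        """Map non-noise labels onto 0..K-1 preserving order of first size rank."""
        labels = self.labels.copy()
        uniq = np.unique(labels[labels >= 0])
        mapping = {old: new for new, old in enumerate(uniq)}
        out = np.array([mapping.get(l, NOISE_LABEL) for l in labels], dtype=int)
        return ClusterAssignment(self.cell_ids, out, self.source)


MARKER_COLUMNS = [
    "cluster",
    "gene_id",
    "rank_in_cluster",
    "t_stat",
    "pval",
    "pval_adj",
    "log2fc",
]


def validate_marker_table(table: pd.DataFrame) -> None:
    missing = [c for c in MARKER_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"marker table missing columns {missing}")
    for _, grp in table.groupby("cluster"):
        ts = grp.sort_values("rank_in_cluster")["t_stat"].to_numpy()
        if np.any(np.diff(ts) > 1e-9):
            raise ValueError("t statistics must be non-increasing with rank")
    if np.any(table["pval_adj"].to_numpy() + 1e-12 < table["pval"].to_numpy()):
        raise ValueError("adjusted p-values cannot be smaller than raw p-values")
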