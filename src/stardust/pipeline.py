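"""Four-pass orchestration: gene selection -> CGNNN -> layout -> DBSCAN -> DE.

Pass 1 seeds the network with the genes carrying the largest absolute PCA
loadings.  Passes 2 and 3 replace them with differentially expressed genes
from the previous pass's clusters, which rewires the network and refines
the clusters.  Pass 4 rebuilds the network from the top cluster-specific
upregulated markers with rank-decayed connectivity and is used only to
place those genes: cell coordinates and cluster labels are taken from pass
3, and gene positions are mapped from pass-4 space back into pass-3 space
with per-cluster KNN regression.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, io_prep, markers as markers_mod, network, sampling
from .datatypes import (
    ClusterAssignment,
    CountMatrix,
    Embedding2D,
    GeneSelection,
    NormalizedMatrix,
)
from .evaluation import ari
from .layout import StageSchedule, layout_graph
from .network import PCAEmbedding

log = logging.getLogger(__name__)

__all__ = ["StardustConfig", "StardustResult", "run_stardust",
           "project_genes", "project_genes_external", "compute_umap"]

N_PASSES = 4


@dataclass
class StardustConfig:
    seed: int = 0
    # preprocessing
    n_top_hvgs: int = 500
    # network
    pca_components: int = 500
    knn_k: int = 20
    gene_top_n: int = 10
    exact_nn: bool | None = None
    # subsampling
    sps: bool = True
    sps_threshold: int = sampling.SPS_SKIP_THRESHOLD
    sps_p_l: float = 0.3
    sps_p_u: float = 0.9
    sps_k_scale: float = 500.0
    # per-pass gene selection
    genes_per_pass: int = 500
    p_adj_max: float = 0.5
    lfc_min: float = 1.2
    top_markers_n: int = 20
    # layout
    edge_cut: float = 0.8
    layout_backend: str = "anneal"
    schedule: StageSchedule | None = None
    # clustering
    dbscan_eps: float | None = None
    dbscan_min_samples: int = 20
    # gene projection
    knn_regression_k: int = 5

    def to_manifest(self) -> dict:
        d = asdict(self)
        if self.schedule is not None:
            d["schedule"] = {name: asdict(stage)
                             for name, stage in self.schedule.stages()}
        return d


@dataclass
class StardustResult:
    cell_coords: Embedding2D
    gene_coords: Embedding2D
    labels: ClusterAssignment
    markers: pd.DataFrame
    top_markers: pd.DataFrame
    pass_log: list[dict]
    config: StardustConfig
    sampled_cell_ids: np.ndarray
    pass_embeddings: dict = field(default_factory=dict)

    def coordinates_frame(self) -> pd.DataFrame:
        cells = self.cell_coords.to_frame()
        label_map = dict(zip(self.labels.cell_ids, self.labels.labels))
        cells["cluster"] = [label_map[c] for c in cells["node_id"]]
        genes = self.gene_coords.to_frame()
        gene_cluster = getattr(self.gene_coords, "_clusters", {})
        genes["cluster"] = [gene_cluster.get(g, -1) for g in genes["node_id"]]
        return pd.concat([cells, genes], ignore_index=True)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.coordinates_frame().to_csv(outdir / "coordinates.csv", index=False)
        self.markers.to_csv(outdir / "markers.csv", index=False)
        manifest = {"config": self.config.to_manifest(),
                    "pass_log": self.pass_log,
                    "n_cells": int(self.labels.cell_ids.size),
                    "n_clusters": int(self.labels.n_clusters)}
        (outdir / "run-manifest.json").write_text(json.dumps(manifest, indent=2))


def _subset_norm(norm: NormalizedMatrix, cell_ids) -> NormalizedMatrix:
    idx = norm.cell_index(cell_ids)
    return NormalizedMatrix(norm.values[idx], norm.cell_ids[idx],
                            norm.gene_ids, norm.median_total)


def _subset_genes(norm: NormalizedMatrix, gene_ids) -> NormalizedMatrix:
    idx = norm.gene_index(gene_ids)
    return NormalizedMatrix(norm.values[:, idx], norm.cell_ids,
                            norm.gene_ids[idx], norm.median_total)


def run_stardust(counts: CountMatrix, config: StardustConfig | None = None
                 ) -> StardustResult:
    """Run the full four-pass co-embedding pipeline on raw counts."""
    cfg = config or StardustConfig()
    norm = io_prep.preprocess(counts)
    log.info("preprocessed: %d cells x %d genes", norm.n_cells, norm.n_genes)

    hvgs = io_prep.select_hvgs(norm, n_top=min(cfg.n_top_hvgs, norm.n_genes))
    norm_hvg = _subset_genes(norm, hvgs.gene_ids)

    # one PCA over all cells: drives the cell kNN graph, the pass-1 gene
    # selection, and the post-hoc neighbor queries for held-out cells
    pca_all = network.compute_pca(norm_hvg, n_comp=cfg.pca_components,
                                  seed=cfg.seed)

    if cfg.sps and norm.n_cells > cfg.sps_threshold:
        plan = sampling.sps_subsample(norm_hvg, seed=cfg.seed, p_l=cfg.sps_p_l,
                                      p_u=cfg.sps_p_u, k_scale=cfg.sps_k_scale)
        sampled_ids = plan.sampled_cell_ids
    else:
        sampled_ids = norm.cell_ids
    sampled_idx = norm.cell_index(sampled_ids)
    pca_sampled = PCAEmbedding(
        scores=pca_all.scores[sampled_idx], loadings=pca_all.loadings,
        explained_variance=pca_all.explained_variance,
        cell_ids=sampled_ids, gene_ids=pca_all.gene_ids)
    norm_s = _subset_norm(norm, sampled_ids)

    cell_edges = network.build_cell_edges(
        pca_sampled, k=min(cfg.knn_k, len(sampled_ids) - 1),
        exact=cfg.exact_nn, seed=cfg.seed)

    pca_selection = network.pca_gene_selection(pca_all, cfg.genes_per_pass)
    genes = pca_selection
    labels_prev: ClusterAssignment | None = None
    marker_table: pd.DataFrame | None = None
    pass_log: list[dict] = []
    embeddings: dict[int, Embedding2D] = {}
    labels_by_pass: dict[int, ClusterAssignment] = {}

    for p in range(1, N_PASSES + 1):
        if p == N_PASSES:
            top = markers_mod.top_markers(marker_table, cfg.top_markers_n)
            gene_order = pd.unique(top["gene_id"])
            graph = network.CellGeneGraph(sampled_ids, gene_order)
            graph.add_cell_cell_edges(cell_edges)
            graph.add_cell_gene_edges(network.build_gene_edges_pass4(
                top, labels_prev, norm_s, gene_order))
        else:
            graph = network.CellGeneGraph(sampled_ids, genes.gene_ids)
            graph.add_cell_cell_edges(cell_edges)
            graph.add_cell_gene_edges(network.build_gene_edges(
                norm_s, genes, n=cfg.gene_top_n))
        graph.validate()

        emb = layout_graph(graph, seed=cfg.seed + 1000 * p,
                           edge_cut=cfg.edge_cut, schedule=cfg.schedule,
                           backend=cfg.layout_backend)
        embeddings[p] = emb
        entry = {"pass": p, "gene_set_size": int(graph.n_genes),
                 "n_edges": int(graph.n_edges)}

        if p < N_PASSES:
            labels = clustering.dbscan_embed(
                emb, eps=cfg.dbscan_eps,
                min_samples=min(cfg.dbscan_min_samples, len(sampled_ids) - 1))
            labels_by_pass[p] = labels
            entry["n_clusters"] = labels.n_clusters
            entry["noise_cells"] = int((labels.labels < 0).sum())
            if labels_prev is not None:
                entry["ari_vs_previous"] = ari(labels.labels, labels_prev.labels)
            if labels.n_clusters >= 2:
                marker_table = markers_mod.rank_genes(norm_s, labels)
                genes = markers_mod.select_pass_genes(
                    marker_table, p_adj_max=cfg.p_adj_max, lfc_min=cfg.lfc_min,
                    cap=cfg.genes_per_pass, fallback=pca_selection)
            else:
                log.warning("pass %d found %d clusters; keeping previous gene set",
                            p, labels.n_clusters)
                if marker_table is None:
                    raise RuntimeError(
                        f"pass {p}: clustering degenerated to "
                        f"{labels.n_clusters} cluster(s) and no earlier marker "
                        "table exists")
            labels_prev = labels
        pass_log.append(entry)

    labels3 = labels_by_pass[N_PASSES - 1]
    top = markers_mod.top_markers(marker_table, cfg.top_markers_n)
    emb3_cells = embeddings[N_PASSES - 1].restrict("cell")

    # post-hoc assignment of cells held out by subsampling
    leftover = np.array([c for c in norm.cell_ids if c not in set(sampled_ids)],
                        dtype=str)
    if leftover.size:
        post_labels, post_coords = clustering.posthoc_assign(
            leftover, pca_all, labels3, emb3_cells, k=cfg.knn_k)
        all_ids = np.concatenate([labels3.cell_ids, post_labels.cell_ids])
        all_labels = np.concatenate([labels3.labels, post_labels.labels])
        all_source = np.concatenate([labels3.source, post_labels.source])
        all_coords = np.vstack([emb3_cells.coords, post_coords.coords])
    else:
        all_ids, all_labels = labels3.cell_ids, labels3.labels
        all_source, all_coords = labels3.source, emb3_cells.coords
    order = norm.cell_index(all_ids).argsort()
    final_labels = ClusterAssignment(all_ids[order], all_labels[order],
                                     all_source[order])
    cell_coords = Embedding2D(all_ids[order],
                              np.array(["cell"] * all_ids.size),
                              all_coords[order], seed=cfg.seed,
                              edge_cut=cfg.edge_cut)

    gene_coords = project_genes(embeddings[N_PASSES], emb3_cells, labels3, top,
                                K=cfg.knn_regression_k)

    return StardustResult(
        cell_coords=cell_coords, gene_coords=gene_coords, labels=final_labels,
        markers=marker_table, top_markers=top, pass_log=pass_log, config=cfg,
        sampled_cell_ids=sampled_ids,
        pass_embeddings=embeddings,
    )


def _dedupe_markers(top: pd.DataFrame) -> pd.DataFrame:
    """One cluster per gene: a gene marking several clusters keeps its best rank."""
    return (top.sort_values(["rank_in_cluster", "cluster"], kind="stable")
            .drop_duplicates("gene_id"))


def _knn_project(cells_x: np.ndarray, cells_y: np.ndarray, genes_x: np.ndarray,
                 K: int) -> np.ndarray:
    """Fit KNN regressors (one per response axis) and map gene positions."""
    from sklearn.neighbors import KNeighborsRegressor

    K = min(K, cells_x.shape[0])
    out = np.empty((genes_x.shape[0], cells_y.shape[1]))
    for ax in range(cells_y.shape[1]):
        reg = KNeighborsRegressor(n_neighbors=K)
        reg.fit(cells_x, cells_y[:, ax])
        out[:, ax] = reg.predict(genes_x)
    return out


def project_genes(pass4: Embedding2D, pass3: Embedding2D,
                  labels: ClusterAssignment, top: pd.DataFrame,
                  K: int = 5) -> Embedding2D:
    """Map pass-4 gene positions into pass-3 cell space, cluster by cluster.

    For each cluster a KNN regressor is trained from its cells' pass-4
    coordinates (predictors) to each pass-3 coordinate axis (responses,
    fit individually) and applied to the cluster's marker genes' pass-4
    positions.  K is clamped to the cluster size when needed.
    """
    return _project(responses=pass3, pass4=pass4, labels=labels, top=top, K=K)


def project_genes_external(ext: Embedding2D, pass4: Embedding2D,
                           labels: ClusterAssignment, top: pd.DataFrame,
                           K: int = 5) -> Embedding2D:
    """Same regression scheme with an external embedding (e.g. UMAP) as responses."""
    cells = pass4.node_ids[pass4.node_types == "cell"]
    missing = sorted(set(cells) - set(ext.node_ids))
    if missing:
        raise ValueError(f"cells missing from external embedding: {missing[:10]}")
    return _project(responses=ext, pass4=pass4, labels=labels, top=top, K=K)


def _project(responses: Embedding2D, pass4: Embedding2D,
             labels: ClusterAssignment, top: pd.DataFrame, K: int) -> Embedding2D:
    pass4_cells = pass4.restrict("cell")
    pass4_genes = pass4.restrict("gene")
    unique_top = _dedupe_markers(top)

    gene_ids, coords, clusters = [], [], {}
    for c, grp in unique_top.groupby("cluster"):
        members = [m for m in labels.members(c) if m in set(pass4_cells.node_ids)]
        if not members:
            log.warning("project_genes: cluster %s has no cells in the layout", c)
            continue
        cx = pass4_cells.lookup(members)
        cy = responses.lookup(members)
        k_eff = min(K, len(members))
        if k_eff < K:
            log.warning("project_genes: cluster %s has %d < K=%d cells; clamping",
                        c, len(members), K)
        present = [g for g in grp["gene_id"] if g in set(pass4_genes.node_ids)]
        if not present:
            continue
        gx = pass4_genes.lookup(present)
        pred = _knn_project(cx, cy, gx, k_eff)
        gene_ids.extend(present)
        coords.extend(pred)
        clusters.update({g: int(c) for g in present})

    emb = Embedding2D(np.array(gene_ids, dtype=str),
                      np.array(["gene"] * len(gene_ids)),
                      np.array(coords).reshape(-1, 2),
                      seed=pass4.seed, edge_cut=pass4.edge_cut)
    emb._clusters = clusters  # cluster of origin for plotting / export
    return emb


def compute_umap(pca: PCAEmbedding, seed: int = 0, n_neighbors: int = 15
                 ) -> Embedding2D:
    """Convenience UMAP of the cells (library call) as an external embedding."""
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=n_neighbors)
    coords = reducer.fit_transform(pca.scores)
    return Embedding2D(pca.cell_ids, np.array(["cell"] * pca.cell_ids.size),
                       np.asarray(coords, dtype=float), seed=seed)
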