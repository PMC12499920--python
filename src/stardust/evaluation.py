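"""Clustering and embedding quality metrics: NMI, ARI, silhouette."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricReport", "nmi", "ari", "silhouette", "evaluate",
           "marker_colocation"]


@dataclass
class MetricReport:
    nmi: float
    ari: float
    silhouette: float | None
    n_clusters: int

    def to_dict(self) -> dict:
        return {"nmi": self.nmi, "ari": self.ari,
                "silhouette": self.silhouette, "n_clusters": self.n_clusters}


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information, arithmetic-mean normalization.

    Two single-cluster labelings are defined to agree perfectly (NMI 1).
    """
    from sklearn.metrics import normalized_mutual_info_score

    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    if np.unique(labels_a).size == 1 and np.unique(labels_b).size == 1:
        return 1.0
    return float(normalized_mutual_info_score(labels_a, labels_b,
                                              average_method="arithmetic"))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index under the permutation model."""
    from sklearn.metrics import adjusted_rand_score

    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def silhouette(coords, labels) -> float:
    """Mean silhouette score with Euclidean distances.

    Points in singleton clusters contribute 0.  A single cluster overall is
    an error (the score is undefined).
    """
    from sklearn.metrics import silhouette_samples

    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    singleton_clusters = set(uniq[counts == 1])
    multi = ~np.isin(labels, list(singleton_clusters))
    scores = np.zeros(labels.size)
    if np.unique(labels[multi]).size >= 2:
        scores[multi] = silhouette_samples(coords[multi], labels[multi])
    return float(scores.mean())


def marker_colocation(gene_emb, cell_emb, labels, top, per_cluster: int = 5
                      ) -> float:
    """Fraction of projected top markers nearest their own cluster centroid.

    For each cluster's ``per_cluster`` best-ranked markers present in the
    gene embedding, checks whether the projected gene position is closer
    (Euclidean) to its own cluster's cell centroid than to any other.
    """
    cluster_ids = labels.cluster_ids()
    centroids = {c: cell_emb.lookup(labels.members(c)).mean(axis=0)
                 for c in cluster_ids}
    placed = set(gene_emb.node_ids)
    total = hits = 0
    for c, grp in top.groupby("cluster"):
        for gene in grp.sort_values("rank_in_cluster")["gene_id"].head(per_cluster):
            if gene not in placed:
                continue
            p = gene_emb.lookup([gene])[0]
            nearest = min(cluster_ids,
                          key=lambda cc: float(np.linalg.norm(p - centroids[cc])))
            hits += nearest == c
            total += 1
    if total == 0:
        raise ValueError("no projected markers to score")
    return hits / total


def evaluate(coords, labels, truth=None) -> MetricReport:
    """Bundle the metrics for one clustering, optionally against a truth."""
    labels = np.asarray(labels)
    n_clusters = int(np.unique(labels[labels >= 0]).size)
    sil = None
    if coords is not None and np.unique(labels).size >= 2:
        sil = silhouette(coords, labels)
    if truth is not None:
        return MetricReport(nmi(labels, truth), ari(labels, truth), sil, n_clusters)
    return MetricReport(float("nan"), float("nan"), sil, n_clusters)
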