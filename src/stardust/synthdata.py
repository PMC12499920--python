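"""Deterministic synthetic data: NB counts with planted clusters, and
ellipse-shaped positional bin maps with arc-localized gene signals.

Counts are drawn from a negative binomial parameterized by per-gene mean
and a common dispersion; a gene planted as a marker for a cluster has its
mean multiplied by 2**log2fc in that cluster only, so marker sets stay
disjoint across clusters.  Everything is a pure function of its parameters
and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CountMatrix

__all__ = ["SyntheticTruth", "simulate_counts", "BinMap", "simulate_binmap"]


@dataclass
class SyntheticTruth:
    labels: np.ndarray
    marker_map: dict[int, list[str]]
    params: dict = field(default_factory=dict)


def simulate_counts(
    n_cells: int = 1000,
    n_genes: int = 2000,
    n_clusters: int = 5,
    markers_per_cluster: int = 50,
    log2fc: float = 2.0,
    nb_dispersion: float = 0.3,
    rare_fraction: float | None = None,
    base_mean_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial counts with planted clusters and marker genes.

    ``nb_dispersion`` is the NB size/shape parameter alpha in the
    var = mu + alpha*mu^2 parameterization.  When ``rare_fraction`` is set,
    the last cluster is sized to that fraction of the cells and the rest
    are split evenly.
    """
    if markers_per_cluster * n_clusters > n_genes:
        raise ValueError("not enough genes for disjoint marker sets")
    if n_clusters < 1 or n_cells < n_clusters:
        raise ValueError("need at least one cell per cluster")
    rng = np.random.default_rng(seed)

    if rare_fraction is not None:
        if not 0 < rare_fraction < 1:
            raise ValueError("rare_fraction must be in (0,1)")
        n_rare = max(1, int(round(rare_fraction * n_cells)))
        sizes = [0] * n_clusters
        sizes[-1] = n_rare
        rest, extras = divmod(n_cells - n_rare, n_clusters - 1)
        for i in range(n_clusters - 1):
            sizes[i] = rest + (1 if i < extras else 0)
    else:
        rest, extras = divmod(n_cells, n_clusters)
        sizes = [rest + (1 if i < extras else 0) for i in range(n_clusters)]
    labels = np.repeat(np.arange(n_clusters), sizes)

    base_mean = rng.uniform(*base_mean_range, size=n_genes)
    marker_map: dict[int, list[str]] = {}
    gene_ids = np.array([f"gene{g:05d}" for g in range(n_genes)])
    mean_matrix = np.tile(base_mean, (n_clusters, 1))
    for c in range(n_clusters):
        idx = np.arange(c * markers_per_cluster, (c + 1) * markers_per_cluster)
        mean_matrix[c, idx] *= 2.0 ** log2fc
        marker_map[c] = list(gene_ids[idx])

    mu = mean_matrix[labels]  # (n_cells, n_genes)
    if nb_dispersion > 0:
        # NB as Gamma-Poisson: shape r = 1/alpha, scale mu/r
        r = 1.0 / nb_dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = np.array([f"cell{c:05d}" for c in range(n_cells)])
    truth = SyntheticTruth(
        labels=labels,
        marker_map=marker_map,
        params=dict(
            n_cells=n_cells, n_genes=n_genes, n_clusters=n_clusters,
            markers_per_cluster=markers_per_cluster, log2fc=log2fc,
            nb_dispersion=nb_dispersion, rare_fraction=rare_fraction, seed=seed,
        ),
    )
    return CountMatrix(counts, cell_ids, gene_ids), truth


@dataclass
class BinMap:
    """Positional bins with probabilistic gene-to-bin mapping scores."""

    bin_ids: np.ndarray
    bin_coords: np.ndarray  # (n_bins, 2 or 3)
    scores: "object"  # pandas DataFrame genes x bins

    def __post_init__(self) -> None:
        self.bin_ids = np.asarray(self.bin_ids, dtype=str)
        self.bin_coords = np.asarray(self.bin_coords, dtype=float)
        if self.bin_coords.shape[0] != self.bin_ids.size:
            raise ValueError("one coordinate row per bin required")
        if list(self.scores.columns) != list(self.bin_ids):
            raise ValueError("score columns must match bin ids")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("non-finite mapping scores")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.scores.index.to_numpy()


def simulate_binmap(
    n_bins: int = 200,
    n_clusters: int = 5,
    genes_per_cluster: int = 20,
    noise_sd: float = 0.1,
    arc_width: float = 0.6,
    seed: int = 0,
) -> tuple[BinMap, SyntheticTruth]:
    """Bins on an ellipse; each cluster's genes peak in one contiguous arc.

    The signal for a gene of cluster c is a Gaussian bump (in angle) centered
    on the cluster's arc center with sd ``arc_width/2``, plus iid Gaussian
    noise of sd ``noise_sd``.  The planted truth records, per cluster, the
    bins whose angular distance to the arc center is below ``arc_width``.
    """
    import pandas as pd

    if n_bins < 10:
        raise ValueError("need at least 10 bins")
    rng = np.random.default_rng(seed)

    theta = np.linspace(0, 2 * np.pi, n_bins, endpoint=False)
    coords = np.column_stack([2.0 * np.cos(theta), 1.0 * np.sin(theta)])
    bin_ids = np.array([f"bin{b:04d}" for b in range(n_bins)])

    centers = np.linspace(0, 2 * np.pi, n_clusters, endpoint=False)
    gene_ids, rows, labels = [], [], []
    for c, center in enumerate(centers):
        ang = np.angle(np.exp(1j * (theta - center)))  # wrapped difference
        bump = np.exp(-0.5 * (ang / (arc_width / 2)) ** 2)
        for g in range(genes_per_cluster):
            gene_ids.append(f"zgene_c{c}_{g:02d}")
            rows.append(bump + rng.normal(0, noise_sd, size=n_bins))
            labels.append(c)
    scores = pd.DataFrame(np.array(rows), index=gene_ids, columns=bin_ids)

    arc_masks = {}
    for c, center in enumerate(centers):
        ang = np.abs(np.angle(np.exp(1j * (theta - center))))
        arc_masks[c] = ang < arc_width
    truth = SyntheticTruth(
        labels=np.array(labels),
        marker_map={c: [g for g, l in zip(gene_ids, labels) if l == c]
                    for c in range(n_clusters)},
        params=dict(n_bins=n_bins, n_clusters=n_clusters, noise_sd=noise_sd,
                    arc_width=arc_width, seed=seed, arc_masks=arc_masks),
    )
    return BinMap(bin_ids, coords, scores), truth
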