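"""Spatial zonation of cell-type clusters on a positional-bin map.

Probabilistic gene-to-bin mapping scores (e.g. from an optimal-transport
cartography run on a virtual embryo) are combined per cluster with
Stouffer's method: each marker gene's score vector is standardized to
z-scores across bins and the cluster score of a bin is sum_g z_gb / sqrt(G).
The module also provides threshold binarization of those scores, Pearson
cluster-correspondence between assays, and a bootstrapped decision-tree
regression that predicts bin coordinates from marker-gene scores, tracked
by RMSE.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import BinMap

log = logging.getLogger(__name__)

__all__ = [
    "read_binmap",
    "stouffer_scores",
    "binarize_scores",
    "cluster_correspondence",
    "predict_coordinates_rmse",
]


def read_binmap(scores_path, coords_path, sep: str = ",") -> BinMap:
    """Load a bin map from a genes x bins score table and a bin-coordinate table."""
    scores = pd.read_csv(scores_path, sep=sep, index_col=0)
    coords = pd.read_csv(coords_path, sep=sep, index_col=0)
    coords = coords.loc[scores.columns]
    return BinMap(scores.columns.to_numpy(), coords.to_numpy(), scores)


def stouffer_scores(binmap: BinMap, genes) -> np.ndarray:
    """Stouffer-combined per-bin score for a gene set.

    Each gene's score row is z-scored across bins; constant rows carry no
    positional information and are dropped with a warning.  The combined
    statistic is sum_g z_gb / sqrt(G) for each bin b.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("need at least one gene")
    missing = [g for g in genes if g not in binmap.scores.index]
    if missing:
        raise KeyError(f"genes missing from bin map: {missing[:10]}")
    rows = binmap.scores.loc[genes].to_numpy(dtype=float)
    sd = rows.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.warning("stouffer_scores: dropping %d constant-score genes",
                    int((~keep).sum()))
    rows, sd = rows[keep], sd[keep]
    if rows.shape[0] == 0:
        raise ValueError("all gene score rows are constant")
    z = (rows - rows.mean(axis=1, keepdims=True)) / sd[:, None]
    return z.sum(axis=0) / np.sqrt(z.shape[0])


def binarize_scores(scores, threshold: float) -> np.ndarray:
    """Boolean mask: score strictly above the (manually calibrated) threshold."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    return scores > threshold


def cluster_correspondence(means_a: pd.DataFrame, means_b: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between cluster-wise mean expression vectors of two assays.

    Rows are clusters, columns the shared gene panel (identical in both
    inputs).  Zero-variance mean vectors give undefined correlations,
    recorded as NaN.
    """
    if list(means_a.columns) != list(means_b.columns):
        raise ValueError("the two assays must share an identical gene panel")
    out = pd.DataFrame(index=means_a.index, columns=means_b.index, dtype=float)
    for ca, va in means_a.iterrows():
        for cb, vb in means_b.iterrows():
            x, y = va.to_numpy(float), vb.to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                out.loc[ca, cb] = np.nan
            else:
                out.loc[ca, cb] = float(np.corrcoef(x, y)[0, 1])
    return out


def predict_coordinates_rmse(binmap: BinMap, feature_genes, n_boot: int = 50,
                             seed: int = 0, tree_kwargs: dict | None = None
                             ) -> pd.DataFrame:
    """Bootstrapped RMSE of predicting bin coordinates from gene scores.

    For each of ``n_boot`` replicates, bins are resampled with replacement
    to form the training set and the out-of-bag bins form validation; a
    decision-tree regressor per coordinate maps the feature genes' mapping
    scores to that coordinate.  Replicates with an empty out-of-bag set are
    redrawn.  Returns a DataFrame (n_boot rows) with one RMSE column per
    coordinate axis and a ``null`` column per axis (RMSE of predicting the
    training mean).
    """
    from sklearn.tree import DecisionTreeRegressor

    feature_genes = list(feature_genes)
    X = binmap.scores.loc[feature_genes].to_numpy(float).T  # bins x genes
    Y = binmap.bin_coords
    n_bins, n_axes = Y.shape
    rng = np.random.default_rng(seed)
    tree_kwargs = tree_kwargs or {}

    records = []
    for _ in range(n_boot):
        while True:
            train = rng.integers(0, n_bins, size=n_bins)
            oob = np.setdiff1d(np.arange(n_bins), train)
            if oob.size:
                break
            log.info("predict_coordinates_rmse: empty out-of-bag set, redrawing")
        row = {}
        for ax in range(n_axes):
            tree = DecisionTreeRegressor(random_state=int(rng.integers(2**31)),
                                         **tree_kwargs)
            tree.fit(X[train], Y[train, ax])
            pred = tree.predict(X[oob])
            row[f"rmse_axis{ax}"] = float(np.sqrt(np.mean((pred - Y[oob, ax]) ** 2)))
            row[f"null_axis{ax}"] = float(
                np.sqrt(np.mean((Y[train, ax].mean() - Y[oob, ax]) ** 2)))
        records.append(row)
    return pd.DataFrame(records)


def write_correspondence(matrix: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path)
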