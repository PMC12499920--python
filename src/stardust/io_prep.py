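"""Reading expression matrices and the standard preprocessing chain.

The preprocessing follows the usual UMI workflow: drop low-complexity cells
(cells expressing fewer than 30% of the average number of expressed genes),
drop genes detected in fewer than three cells, scale each cell's counts to
the median pre-normalization total, log1p-transform, and pick highly
variable genes by Cell-Ranger-flavor normalized dispersion.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, GeneSelection, NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "read_mtx",
    "read_dense",
    "read_h5ad",
    "write_mtx",
    "write_dense",
    "filter_cells",
    "filter_genes",
    "normalize_log",
    "select_hvgs",
    "preprocess",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_mtx(matrix_path, barcodes_path=None, features_path=None,
             cells_as_rows: bool = False) -> CountMatrix:
    """Read a Matrix Market matrix with barcode/feature TSV sidecars.

    The CellRanger convention stores genes as rows; set ``cells_as_rows``
    if the matrix is already oriented cells x genes.  Sidecar paths default
    to ``barcodes.tsv`` / ``features.tsv`` (or ``genes.tsv``) next to the
    matrix; ``.gz`` variants are picked up automatically.
    """
    from scipy.io import mmread

    matrix_path = Path(matrix_path)
    folder = matrix_path.parent

    def _find(name_options):
        for name in name_options:
            for suffix in ("", ".gz"):
                p = folder / (name + suffix)
                if p.exists():
                    return p
        raise FileNotFoundError(f"no sidecar among {name_options} in {folder}")

    barcodes_path = Path(barcodes_path) if barcodes_path else _find(["barcodes.tsv"])
    features_path = Path(features_path) if features_path else _find(
        ["features.tsv", "genes.tsv"])

    mat = sp.csr_matrix(mmread(str(matrix_path)))
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).to_numpy()
    feat = pd.read_csv(features_path, sep="\t", header=None)
    genes = feat[0].astype(str).to_numpy()
    if not cells_as_rows:
        mat = sp.csr_matrix(mat.T)
    return CountMatrix(mat, barcodes, genes)


def read_dense(path, sep: str | None = None, cells_as_rows: bool = True) -> CountMatrix:
    """Read a delimited counts table with a header row and an id column."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not cells_as_rows:
        df = df.T
    return CountMatrix(df.to_numpy(), df.index.astype(str), df.columns.astype(str))


def read_h5ad(path) -> CountMatrix:
    """Read a single-cell HDF5 container (AnnData .h5ad), using .X as counts."""
    import anndata as ad

    adata = ad.read_h5ad(path)
    x = adata.X
    if sp.issparse(x):
        x = sp.csr_matrix(x)
    else:
        x = np.asarray(x)
    return CountMatrix(x, adata.obs_names.to_numpy(), adata.var_names.to_numpy())


def write_mtx(counts: CountMatrix, folder) -> None:
    from scipy.io import mmwrite

    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    mmwrite(str(folder / "matrix.mtx"), sp.csr_matrix(counts.values).T.tocoo())
    pd.Series(counts.cell_ids).to_csv(folder / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    pd.DataFrame({"id": counts.gene_ids, "name": counts.gene_ids}).to_csv(
        folder / "features.tsv", sep="\t", header=False, index=False)


def write_dense(matrix, path, sep: str = ",") -> None:
    """Write a CountMatrix or NormalizedMatrix as a delimited cells x genes table."""
    values = matrix.dense() if hasattr(matrix, "dense") else matrix.values
    pd.DataFrame(np.asarray(values), index=matrix.cell_ids,
                 columns=matrix.gene_ids).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# filters and normalization
# ---------------------------------------------------------------------------

def filter_cells(counts: CountMatrix) -> CountMatrix:
    """Drop cells expressing fewer than 30% of the mean expressed-gene count.

    A gene counts as expressed in a cell when its count is > 0.  The mean
    is taken over all input cells; cells strictly below 0.3x that mean are
    removed.
    """
    if counts.n_cells == 0:
        raise ValueError("empty count matrix")
    if sp.issparse(counts.values):
        expressed = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    else:
        expressed = (counts.dense() > 0).sum(axis=1)
    threshold = 0.3 * expressed.mean()
    keep = expressed >= threshold
    if not keep.any():
        raise ValueError("empty after filtering: no cell reaches 30% of the mean "
                         "expressed-gene count")
    if (~keep).sum():
        log.info("filter_cells: removed %d of %d cells (threshold %.2f expressed genes)",
                 int((~keep).sum()), counts.n_cells, threshold)
    return counts.subset(cell_mask=keep)


def filter_genes(counts: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells."""
    if counts.n_cells == 0:
        raise ValueError("empty count matrix")
    if sp.issparse(counts.values):
        detected = np.asarray((counts.values > 0).sum(axis=0)).ravel()
    else:
        detected = (counts.dense() > 0).sum(axis=0)
    keep = detected >= min_cells
    return counts.subset(gene_mask=keep)


def normalize_log(counts: CountMatrix) -> NormalizedMatrix:
    """Scale each cell to the median pre-normalization total, then log1p."""
    dense = counts.dense().astype(np.float64)
    totals = dense.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts cannot be normalized: "
            f"{list(counts.cell_ids[zero[:10]])}")
    median_total = float(np.median(totals))
    scaled = dense * (median_total / totals)[:, None]
    return NormalizedMatrix(np.log1p(scaled), counts.cell_ids, counts.gene_ids,
                            median_total)


def select_hvgs(norm: NormalizedMatrix, n_top: int = 500) -> GeneSelection:
    """Top ``n_top`` genes by Cell-Ranger-flavor normalized dispersion.

    Dispersion is computed on expm1-back-transformed expression, binned by
    mean, and z-scored within bins (median/MAD), the standard Cell Ranger
    recipe; delegates to scanpy's implementation.
    """
    import anndata as ad
    import scanpy as sc

    if n_top > norm.n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {norm.n_genes}")
    adata = ad.AnnData(X=norm.values.copy(),
                       obs=pd.DataFrame(index=norm.cell_ids),
                       var=pd.DataFrame(index=norm.gene_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="cell_ranger")
    scores = adata.var["dispersions_norm"].to_numpy(dtype=float)
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    order = np.argsort(-scores, kind="stable")[:n_top]
    return GeneSelection(norm.gene_ids[order], "hvg_dispersion", scores[order])


def preprocess(counts: CountMatrix) -> NormalizedMatrix:
    """Cell filter, then gene filter, then median normalization + log1p."""
    filtered = filter_genes(filter_cells(counts))
    if filtered.n_genes == 0:
        raise ValueError("no genes survive the detection filter")
    return normalize_log(filtered)
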