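"""Per-cluster marker detection with the overestimated-variance t-test.

Each cluster is compared one-vs-rest.  The overestimated-variance variant
divides BOTH variance terms by the focal group's size n_g,

    t = (mu_g - mu_r) / sqrt( s_g^2/n_g + s_r^2/n_g ),

which inflates the standard error of the rest group whenever the rest is
larger, making the test conservative.  Degrees of freedom follow
Welch-Satterthwaite with n_g in both terms; p-values are two-sided and
Benjamini-Hochberg adjusted across genes within each comparison.  Fold
changes are computed on expm1-back-transformed mean log expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import MARKER_COLUMNS, ClusterAssignment, GeneSelection, NormalizedMatrix
from .network import pca_gene_selection  # noqa: F401  (fallback path)

log = logging.getLogger(__name__)

__all__ = ["rank_genes", "select_pass_genes", "top_markers",
           "overestim_var_ttest"]

VAR_FLOOR = 1e-9
LFC_EPS = 1e-9


def overestim_var_ttest(group: np.ndarray, rest: np.ndarray):
    """Vectorized overestimated-variance t-test, columns = genes.

    Returns (t, pval).  Both variance terms are divided by the group size;
    variances are floored at 1e-9 so constant genes yield finite t.
    """
    n_g = group.shape[0]
    mu_g, mu_r = group.mean(axis=0), rest.mean(axis=0)
    s2_g = np.maximum(group.var(axis=0, ddof=1), VAR_FLOOR)
    s2_r = np.maximum(rest.var(axis=0, ddof=1), VAR_FLOOR)
    v1, v2 = s2_g / n_g, s2_r / n_g
    t = (mu_g - mu_r) / np.sqrt(v1 + v2)
    dof = (v1 + v2) ** 2 / ((v1 ** 2 + v2 ** 2) / (n_g - 1))
    pval = 2 * stats.t.sf(np.abs(t), dof)
    return t, pval


def rank_genes(norm: NormalizedMatrix, labels: ClusterAssignment) -> pd.DataFrame:
    """One-vs-rest marker table over all clusters.

    Noise cells (label -1) are excluded from every comparison.  Clusters
    with fewer than 2 cells are skipped with a warning.  Output columns are
    ``MARKER_COLUMNS``; within each cluster genes are ranked by decreasing
    t statistic.
    """
    cell_pos = norm.cell_index(labels.cell_ids)
    X = norm.values[cell_pos]
    lab = labels.labels
    clusters = [c for c in np.unique(lab) if c >= 0]
    usable = lab >= 0
    if len([c for c in clusters if (lab == c).sum() >= 2]) < 2:
        raise ValueError("need at least 2 clusters with at least 2 cells each")

    frames = []
    for c in clusters:
        in_c = lab == c
        if in_c.sum() < 2:
            log.warning("rank_genes: cluster %s has a single cell; skipped", c)
            continue
        rest_mask = usable & ~in_c
        if rest_mask.sum() < 2:
            log.warning("rank_genes: rest of cluster %s too small; skipped", c)
            continue
        grp, rest = X[in_c], X[rest_mask]
        t, pval = overestim_var_ttest(grp, rest)
        _, padj, _, _ = multipletests(pval, method="fdr_bh")
        lfc = np.log2((np.expm1(grp.mean(axis=0)) + LFC_EPS)
                      / (np.expm1(rest.mean(axis=0)) + LFC_EPS))
        order = np.argsort(-t, kind="stable")
        frames.append(pd.DataFrame({
            "cluster": c,
            "gene_id": norm.gene_ids[order],
            "rank_in_cluster": np.arange(1, order.size + 1),
            "t_stat": t[order],
            "pval": pval[order],
            "pval_adj": padj[order],
            "log2fc": lfc[order],
        }))
    return pd.concat(frames, ignore_index=True)[MARKER_COLUMNS]


def select_pass_genes(markers: pd.DataFrame, p_adj_max: float = 0.5,
                      lfc_min: float = 1.2, cap: int = 500,
                      fallback: GeneSelection | None = None) -> GeneSelection:
    """Genes driving the next pass: adjusted P < p_adj_max AND log2fc > lfc_min.

    Both inequalities are strict.  The union over clusters is deduplicated
    keeping each gene's best (largest-t) record and truncated to ``cap``.
    If nothing passes, the supplied fallback selection is returned with a
    warning (the pipeline passes its PCA-loading selection here).

    The p_adj_max default of 0.5 follows the published workflow; note that
    0.05 is the conventional significance cutoff — both are exposed.
    """
    if markers.empty:
        raise ValueError("empty marker table")
    passed = markers[(markers["pval_adj"] < p_adj_max)
                     & (markers["log2fc"] > lfc_min)]
    if passed.empty:
        if fallback is not None:
            log.warning("select_pass_genes: no gene passed; falling back to %s",
                        fallback.method)
            return fallback
        raise ValueError("no gene passes the DE filters and no fallback given")
    best = (passed.sort_values("t_stat", ascending=False, kind="stable")
            .drop_duplicates("gene_id").head(cap))
    return GeneSelection(best["gene_id"].to_numpy(), "de",
                         best["t_stat"].to_numpy())


def top_markers(markers: pd.DataFrame, per_cluster: int = 20) -> pd.DataFrame:
    """Top upregulated markers per cluster, ranks re-numbered 1..m."""
    out = []
    for c, grp in markers.groupby("cluster", sort=True):
        up = grp[grp["log2fc"] > 0].sort_values("rank_in_cluster").head(per_cluster)
        up = up.copy()
        up["rank_in_cluster"] = np.arange(1, len(up) + 1)
        out.append(up)
    return pd.concat(out, ignore_index=True)[MARKER_COLUMNS]
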