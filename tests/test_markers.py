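import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stardust.datatypes import ClusterAssignment, GeneSelection, NormalizedMatrix
from stardust.markers import (
    overestim_var_ttest,
    rank_genes,
    select_pass_genes,
    top_markers,
)


def oracle_t(group, rest):
    """Independently coded overestimated-variance t-test on one gene."""
    group, rest = np.asarray(group, float), np.asarray(rest, float)
    n_g = len(group)
    v1 = max(group.var(ddof=1), 1e-9) / n_g
    v2 = max(rest.var(ddof=1), 1e-9) / n_g
    t = (group.mean() - rest.mean()) / np.sqrt(v1 + v2)
    dof = (v1 + v2) ** 2 / ((v1 ** 2 + v2 ** 2) / (n_g - 1))
    return t, 2 * stats.t.sf(abs(t), dof)


def oracle_bh(pvals):
    """Brute-force Benjamini-Hochberg: sort, scale, cumulative minimum."""
    pvals = np.asarray(pvals, float)
    m = len(pvals)
    order = np.argsort(pvals)
    scaled = pvals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def make_norm(values):
    values = np.asarray(values, float)
    return NormalizedMatrix(values,
                            [f"c{i}" for i in range(values.shape[0])],
                            [f"g{j}" for j in range(values.shape[1])], 1.0)


class TestTTest:
    def test_hand_vectors_match_oracle(self):
        g = np.array([[1.0], [2.0], [3.0]])
        r = np.array([[4.0], [5.0], [6.0], [7.0]])
        t, p = overestim_var_ttest(g, r)
        t_o, p_o = oracle_t(g[:, 0], r[:, 0])
        assert t[0] == pytest.approx(t_o)
        assert p[0] == pytest.approx(p_o)

    def test_identical_means_give_zero_t_unit_p(self):
        g = np.array([[1.0], [3.0]])
        r = np.array([[3.0], [1.0]])
        t, p = overestim_var_ttest(g, r)
        assert t[0] == 0.0
        assert p[0] == pytest.approx(1.0)

    def test_upregulated_group_positive_t(self):
        g = np.full((4, 1), 2.0)
        r = np.zeros((4, 1))
        t, _ = overestim_var_ttest(g, r)
        assert t[0] > 0

    def test_antisymmetric_in_mean_swap(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1, 0.3, (5, 3))
        b = rng.normal(0, 0.3, (5, 3))
        t_ab, _ = overestim_var_ttest(a, b)
        # swapping group and rest flips the mean difference; with equal
        # group sizes the denominator is symmetric so t flips sign
        t_ba, _ = overestim_var_ttest(b, a)
        assert np.allclose(t_ab, -t_ba)

    @given(st.lists(st.floats(0.001, 0.999), min_size=3, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_bh_matches_bruteforce_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(adj, oracle_bh(pvals))


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(1)
    values = np.abs(rng.normal(1.0, 0.2, size=(60, 30)))
    labels = np.repeat([0, 1, 2], 20)
    # gene j*3 upregulated in cluster j
    for c in range(3):
        values[labels == c, c * 3] += 2.0
    norm = make_norm(values)
    assign = ClusterAssignment(norm.cell_ids, labels)
    return rank_genes(norm, assign)


class TestRankGenes:
    def test_planted_markers_rank_first(self, planted):
        for c in range(3):
            grp = planted[planted["cluster"] == c].sort_values("rank_in_cluster")
            assert grp.iloc[0]["gene_id"] == f"g{c * 3}"
            assert grp.iloc[0]["log2fc"] > 0

    def test_rank_follows_t_ordering(self, planted):
        for _, grp in planted.groupby("cluster"):
            ts = grp.sort_values("rank_in_cluster")["t_stat"].to_numpy()
            assert np.all(np.diff(ts) <= 1e-12)

    def test_adjusted_p_at_least_raw(self, planted):
        assert np.all(planted["pval_adj"] >= planted["pval"] - 1e-15)

    def test_statistics_match_oracle_per_gene(self, planted):
        # recompute one cluster's stats gene by gene with the oracle
        rng = np.random.default_rng(1)
        values = np.abs(rng.normal(1.0, 0.2, size=(60, 30)))
        labels = np.repeat([0, 1, 2], 20)
        for c in range(3):
            values[labels == c, c * 3] += 2.0
        grp0 = planted[planted["cluster"] == 0].set_index("gene_id")
        raw_p = []
        for j in range(30):
            t_o, p_o = oracle_t(values[labels == 0, j], values[labels != 0, j])
            assert grp0.loc[f"g{j}", "t_stat"] == pytest.approx(t_o, rel=1e-9)
            raw_p.append(p_o)
        assert np.allclose(np.sort(grp0["pval_adj"]),
                           np.sort(oracle_bh(raw_p)), rtol=1e-9)

    def test_single_cell_cluster_skipped(self, caplog):
        rng = np.random.default_rng(2)
        values = np.abs(rng.normal(1, 0.2, (21, 5)))
        labels = np.array([0] * 10 + [1] * 10 + [2])
        norm = make_norm(values)
        with caplog.at_level("WARNING"):
            table = rank_genes(norm, ClusterAssignment(norm.cell_ids, labels))
        assert 2 not in set(table["cluster"])

    def test_noise_cells_excluded(self):
        rng = np.random.default_rng(3)
        values = np.abs(rng.normal(1, 0.2, (40, 5)))
        labels = np.array([0] * 15 + [1] * 15 + [-1] * 10)
        values[30:, 0] += 100.0  # huge signal carried only by noise cells
        norm = make_norm(values)
        table = rank_genes(norm, ClusterAssignment(norm.cell_ids, labels))
        g0 = table[(table["cluster"] == 0) & (table["gene_id"] == "g0")]
        assert abs(float(g0["t_stat"].iloc[0])) < 5  # noise signal not leaked


class TestSelectPassGenes:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["cluster", "gene_id",
                                           "rank_in_cluster", "t_stat",
                                           "pval", "pval_adj", "log2fc"])

    def test_hand_filtering(self):
        table = self._table([
            (0, "a", 1, 9.0, 1e-4, 1e-3, 2.0),   # passes
            (0, "b", 2, 8.0, 1e-4, 1e-3, 1.2),   # boundary lfc: excluded
            (0, "c", 3, 7.0, 0.2, 0.6, 3.0),     # p_adj too high
            (1, "d", 1, 6.0, 1e-3, 0.01, 1.3),   # passes
            (1, "a", 2, 5.0, 1e-3, 0.01, 1.5),   # duplicate of a, lower t
        ])
        sel = select_pass_genes(table, p_adj_max=0.5, lfc_min=1.2)
        assert list(sel.gene_ids) == ["a", "d"]
        assert sel.scores[0] == 9.0  # best record kept for the duplicate

    def test_exact_boundary_excluded(self):
        table = self._table([(0, "a", 1, 5.0, 0.01, 0.5, 1.2)])
        with pytest.raises(ValueError):
            select_pass_genes(table, p_adj_max=0.5, lfc_min=1.2)

    def test_fallback_triggered_when_nothing_passes(self, caplog):
        table = self._table([(0, "a", 1, 5.0, 0.9, 0.95, 0.1)])
        fb = GeneSelection(["x", "y"], "pca_loading", [1.0, 0.5])
        with caplog.at_level("WARNING"):
            sel = select_pass_genes(table, fallback=fb)
        assert sel is fb

    def test_output_subset_of_marker_genes(self):
        rng = np.random.default_rng(4)
        table = self._table([
            (c, f"g{i}", i + 1, float(10 - i), 1e-3, 1e-2,
             float(rng.uniform(1.3, 3)))
            for c in range(2) for i in range(8)
        ])
        sel = select_pass_genes(table, cap=5)
        assert len(sel) == 5
        assert set(sel.gene_ids) <= set(table["gene_id"])


class TestTopMarkers:
    def test_short_cluster_returns_what_exists(self):
        table = pd.DataFrame({
            "cluster": [0] * 5, "gene_id": [f"g{i}" for i in range(5)],
            "rank_in_cluster": range(1, 6), "t_stat": range(9, 4, -1),
            "pval": [0.01] * 5, "pval_adj": [0.02] * 5,
            "log2fc": [1.0, 1.0, 1.0, -0.5, 1.0],
        })
        out = top_markers(table, per_cluster=20)
        assert len(out) == 4  # the downregulated gene is dropped
        assert list(out["rank_in_cluster"]) == [1, 2, 3, 4]

    def test_planted_markers_occupy_top_ranks(self, small_run):
        result, counts, truth = small_run
        top = top_markers(result.markers, per_cluster=10)
        planted = {g for genes in truth.marker_map.values() for g in genes}
        hit = top["gene_id"].isin(planted).mean()
        assert hit >= 0.9
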