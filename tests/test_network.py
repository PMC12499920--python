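import numpy as np
import pandas as pd
import pytest

from stardust import io_prep, network
from stardust.datatypes import (
    CellGeneGraph,
    ClusterAssignment,
    GeneSelection,
    NormalizedMatrix,
)
from stardust.network import PCAEmbedding


def make_norm(values):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(values,
                            [f"c{i}" for i in range(values.shape[0])],
                            [f"g{j}" for j in range(values.shape[1])],
                            median_total=1.0)


@pytest.fixture()
def random_norm():
    rng = np.random.default_rng(0)
    return make_norm(np.abs(rng.normal(1, 0.5, size=(60, 40))))


class TestPCA:
    def test_rank_one_data_on_a_line(self):
        t = np.linspace(0, 1, 30)
        values = np.outer(t, np.array([1.0, 2.0, 3.0]))
        pca = network.compute_pca(make_norm(values), n_comp=2)
        ev = pca.explained_variance
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_n_comp_clamped_to_dimension_bound(self, random_norm):
        pca = network.compute_pca(random_norm, n_comp=500)
        assert pca.n_comp == min(random_norm.n_cells - 1, random_norm.n_genes)

    def test_full_reconstruction_round_trip(self, random_norm):
        pca = network.compute_pca(random_norm, n_comp=40)
        centered = random_norm.values - random_norm.values.mean(axis=0)
        recon = pca.scores @ pca.loadings.T
        assert np.allclose(recon, centered, atol=1e-8)

    def test_loadings_unit_norm(self, random_norm):
        pca = network.compute_pca(random_norm, n_comp=10)
        assert np.allclose(np.linalg.norm(pca.loadings, axis=0), 1.0)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            network.compute_pca(make_norm(np.ones((5, 4))))


class TestPcaGeneSelection:
    def test_matches_bruteforce_max_abs_loading(self):
        loadings = np.array([[0.9, 0.1], [0.2, -0.95], [0.5, 0.5],
                             [-0.1, 0.05], [0.0, 0.0]])
        pca = PCAEmbedding(scores=np.zeros((3, 2)), loadings=loadings,
                           explained_variance=np.ones(2),
                           cell_ids=np.array(["c0", "c1", "c2"]),
                           gene_ids=np.array([f"g{j}" for j in range(5)]))
        sel = network.pca_gene_selection(pca, n_genes=5)
        brute = np.argsort(-np.abs(loadings).max(axis=1), kind="stable")
        assert list(sel.gene_ids) == [f"g{j}" for j in brute]
        assert list(sel.gene_ids)[-1] == "g4"  # zero loadings rank last

    def test_all_genes_is_a_permutation(self, random_norm):
        pca = network.compute_pca(random_norm, n_comp=10)
        sel = network.pca_gene_selection(pca, n_genes=random_norm.n_genes)
        assert set(sel.gene_ids) == set(random_norm.gene_ids)


class TestCellEdges:
    def _pca_from_points(self, points):
        points = np.asarray(points, dtype=float)
        return PCAEmbedding(scores=points, loadings=np.eye(points.shape[1]),
                            explained_variance=np.ones(points.shape[1]),
                            cell_ids=np.array([f"c{i}" for i in range(len(points))]),
                            gene_ids=np.array([f"g{j}" for j in range(points.shape[1])]))

    def test_collinear_points_k1(self):
        pca = self._pca_from_points([[0.0, 0], [1.0, 0], [2.0, 0]])
        pairs = network.build_cell_edges(pca, k=1)
        undirected = {tuple(sorted(p)) for p in pairs}
        assert undirected == {(0, 1), (1, 2)}

    def test_edge_count_union_bound(self):
        rng = np.random.default_rng(1)
        pca = self._pca_from_points(rng.normal(size=(40, 3)))
        pairs = network.build_cell_edges(pca, k=5)
        undirected = {tuple(sorted(p)) for p in pairs}
        assert len(undirected) <= 40 * 5

    def test_exact_equals_bruteforce_knn(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 4))
        pca = self._pca_from_points(pts)
        pairs = network.build_cell_edges(pca, k=3, exact=True)
        got = {tuple(sorted(p)) for p in pairs}
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        expected = set()
        for i in range(30):
            for j in np.argsort(d[i])[:3]:
                expected.add(tuple(sorted((i, int(j)))))
        assert got == expected

    def test_approximate_agrees_with_exact(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 5))
        pca = self._pca_from_points(pts)
        exact = {tuple(sorted(p))
                 for p in network.build_cell_edges(pca, k=5, exact=True)}
        approx = {tuple(sorted(p))
                  for p in network.build_cell_edges(pca, k=5, exact=False, seed=0)}
        overlap = len(exact & approx) / len(exact)
        assert overlap >= 0.9

    def test_k_too_large_rejected(self):
        pca = self._pca_from_points(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            network.build_cell_edges(pca, k=3)


class TestGeneEdges:
    def test_top_n_matches_bruteforce(self):
        values = np.array([[0.1, 5.0], [0.7, 1.0], [0.3, 2.0], [0.9, 0.0]])
        norm = make_norm(values)
        sel = GeneSelection(["g0", "g1"], "pca_loading", [1.0, 0.5])
        pairs = network.build_gene_edges(norm, sel, n=2)
        by_gene = {g: sorted(c for c, gg in pairs if gg == g) for g in (0, 1)}
        assert by_gene[0] == [1, 3]  # 0.9 and 0.7 are the two largest
        assert by_gene[1] == [0, 2]

    def test_degree_exactly_min_n_cells(self, random_norm):
        sel = GeneSelection([f"g{j}" for j in range(5)], "pca_loading",
                            np.ones(5))
        pairs = network.build_gene_edges(random_norm, sel, n=10)
        counts = np.bincount(pairs[:, 1], minlength=5)
        assert np.all(counts == 10)

    def test_single_expressing_cell_always_included_and_deterministic(self):
        values = np.zeros((6, 1))
        values[4, 0] = 3.0
        norm = make_norm(values)
        sel = GeneSelection(["g0"], "pca_loading", [1.0])
        a = network.build_gene_edges(norm, sel, n=4)
        b = network.build_gene_edges(norm, sel, n=4)
        assert np.array_equal(a, b)
        assert 4 in a[:, 0]
        # tie-break over zero-expression cells follows cell order
        assert sorted(a[:, 0]) == [0, 1, 2, 4]


class TestPass4Edges:
    @pytest.mark.parametrize("rank,p", [(1, 4), (10, 4), (11, 3), (20, 3)])
    def test_rank_decay_formula(self, rank, p):
        assert network.pass4_edge_count(rank) == p

    def test_top_ranks_get_at_least_as_many_edges(self):
        counts = [network.pass4_edge_count(i) for i in range(1, 21)]
        assert min(counts[:10]) >= max(counts[10:])

    def test_edges_confined_to_own_cluster(self):
        rng = np.random.default_rng(4)
        norm = make_norm(np.abs(rng.normal(1, 0.3, size=(20, 6))))
        labels = ClusterAssignment(norm.cell_ids,
                                   np.repeat([0, 1], 10))
        markers = pd.DataFrame({
            "cluster": [0, 0, 1],
            "gene_id": ["g0", "g1", "g2"],
            "rank_in_cluster": [1, 11, 1],
            "t_stat": [5.0, 3.0, 4.0],
            "pval": [0.01] * 3, "pval_adj": [0.02] * 3, "log2fc": [2.0] * 3,
        })
        gene_order = np.array(["g0", "g1", "g2"])
        pairs = network.build_gene_edges_pass4(markers, labels, norm, gene_order)
        deg = np.bincount(pairs[:, 1], minlength=3)
        assert list(deg) == [4, 3, 4]
        for c, g in pairs:
            expected_cluster = 0 if gene_order[g] in ("g0", "g1") else 1
            assert labels.labels[c] == expected_cluster


class TestGraphStructure:
    def test_validator_rejects_gene_gene_edges(self, tmp_path):
        graph = CellGeneGraph(["c0", "c1"], ["g0", "g1"])
        graph.add_cell_cell_edges([(0, 1)])
        graph.add_cell_gene_edges([(0, 0)])
        graph.validate()
        edges = pd.DataFrame({"source": ["g0"], "target": ["g1"]})
        edges.to_csv(tmp_path / "edges.tsv", sep="\t", index=False)
        pd.DataFrame({"node_id": ["c0", "c1", "g0", "g1"],
                      "node_type": ["cell", "cell", "gene", "gene"]}).to_csv(
            tmp_path / "types.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="gene-gene"):
            network.read_edge_list(tmp_path / "edges.tsv", tmp_path / "types.tsv")

    def test_no_self_loops_or_duplicates(self):
        graph = CellGeneGraph(["c0", "c1"], [])
        graph.add_cell_cell_edges([(0, 0), (0, 1), (1, 0), (0, 1)])
        assert graph.n_edges == 1

    def test_unit_weights_in_igraph_export(self):
        graph = CellGeneGraph(["c0", "c1"], ["g0"])
        graph.add_cell_cell_edges([(0, 1)])
        graph.add_cell_gene_edges([(0, 0)])
        ig = graph.to_igraph()
        assert set(ig.es["weight"]) == {1.0}

    def test_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(1, 0.4, size=(25, 10)))
        norm_a = make_norm(values)
        perm = rng.permutation(25)
        norm_b = NormalizedMatrix(values[perm],
                                  norm_a.cell_ids[perm], norm_a.gene_ids, 1.0)
        pca_a = network.compute_pca(norm_a, n_comp=5)
        pca_b = network.compute_pca(norm_b, n_comp=5)
        ids_a = {frozenset((norm_a.cell_ids[i], norm_a.cell_ids[j]))
                 for i, j in network.build_cell_edges(pca_a, k=3, exact=True)}
        ids_b = {frozenset((norm_b.cell_ids[i], norm_b.cell_ids[j]))
                 for i, j in network.build_cell_edges(pca_b, k=3, exact=True)}
        assert ids_a == ids_b


class TestInterchange:
    @pytest.fixture()
    def graph(self):
        g = CellGeneGraph(["c0", "c1", "c2"], ["g0", "g1"])
        g.add_cell_cell_edges([(0, 1), (1, 2)])
        g.add_cell_gene_edges([(0, 0), (2, 1)])
        return g

    def test_edge_list_round_trip_bit_exact(self, graph, tmp_path):
        network.write_edge_list(graph, tmp_path / "e.tsv", tmp_path / "t.tsv")
        back = network.read_edge_list(tmp_path / "e.tsv", tmp_path / "t.tsv")
        assert np.array_equal(back.edge_array(), graph.edge_array())
        assert list(back.node_ids) == list(graph.node_ids)

    def test_graphml_round_trip(self, graph, tmp_path):
        network.write_graphml(graph, tmp_path / "g.graphml")
        back = network.read_graphml(tmp_path / "g.graphml")
        got = {frozenset((back.node_ids[a], back.node_ids[b]))
               for a, b in back.edge_array()}
        want = {frozenset((graph.node_ids[a], graph.node_ids[b]))
                for a, b in graph.edge_array()}
        assert got == want
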