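import networkx as nx
import numpy as np
import pytest

from tmegraph.classes import EMPTY_CELL
from tmegraph.histology_map import HistologyMap
from tmegraph.tme_graph import (
    GRAPH_FEATURE_NAMES,
    TileCluster,
    all_pair_features,
    build_pair_graph,
    class_pairs,
    find_clusters,
    graph_features,
)

from _oracles import all_pairs_edges, exhaustive_mst_length, flood_fill_count

F = {name: i for i, name in enumerate(GRAPH_FEATURE_NAMES)}


def _grid_map(grid):
    return HistologyMap("s", np.asarray(grid))


def _node(x, y, cls=1, cid="c"):
    return TileCluster(cid, cls, [(0, 0)], (float(x), float(y)))


class TestFindClusters:
    def test_single_cell_centroid_at_tile_center(self):
        grid = np.full((4, 4), EMPTY_CELL)
        grid[2, 3] = 1
        (cluster,) = find_clusters(_grid_map(grid), 1)
        assert cluster.centroid == (3.5 * 224, 2.5 * 224)
        assert cluster.member_cells == [(2, 3)]

    def test_diagonal_cells_join_under_8_adjacency(self):
        grid = np.full((4, 4), EMPTY_CELL)
        grid[0, 0] = grid[1, 1] = 1
        clusters = find_clusters(_grid_map(grid), 1)
        assert len(clusters) == 1
        assert len(clusters[0].member_cells) == 2

    def test_absent_class_gives_empty_list(self):
        assert find_clusters(_grid_map(np.full((3, 3), EMPTY_CELL)), 5) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_cluster_count_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, 4, size=(20, 20))
        grid[rng.random(grid.shape) < 0.5] = EMPTY_CELL
        for cls in range(4):
            assert len(find_clusters(_grid_map(grid), cls)) == flood_fill_count(grid, cls)

    def test_mean_texture_averaged_over_members(self):
        grid = np.full((2, 2), EMPTY_CELL)
        grid[0, 0] = grid[0, 1] = 2
        tex = {(0, 0): np.ones(6), (0, 1): np.full(6, 3.0)}
        (cluster,) = find_clusters(_grid_map(grid), 2, tex)
        np.testing.assert_allclose(cluster.mean_texture, 2.0)


class TestBuildPairGraph:
    def test_edge_within_radius(self):
        tme = build_pair_graph([_node(0, 0, 1)], [_node(100, 0, 2)], radius=150)
        assert tme.graph.number_of_edges() == 1

    def test_no_edge_beyond_radius(self):
        tme = build_pair_graph([_node(0, 0, 1)], [_node(100, 0, 2)], radius=50)
        assert tme.graph.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_edges_match_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1000, size=(10, 2))
        nodes = [_node(x, y, 1, f"n{i}") for i, (x, y) in enumerate(pts)]
        tme = build_pair_graph(nodes[:5], nodes[5:], radius=400)
        got = {tuple(sorted(e)) for e in tme.graph.edges()}
        assert got == all_pairs_edges(pts, 400)

    def test_simple_graph_invariants(self):
        nodes = [_node(i * 10, 0, 1, f"n{i}") for i in range(5)]
        tme = build_pair_graph(nodes, [], radius=1000)
        g = tme.graph
        assert not any(u == v for u, v in g.edges())
        assert g.number_of_edges() == len(set(map(frozenset, g.edges())))

    def test_nonpositive_radius_is_error(self):
        with pytest.raises(ValueError, match="radius"):
            build_pair_graph([], [], radius=0)


class TestGraphFeatures:
    def test_empty_graph_all_zeros(self):
        tme = build_pair_graph([], [], radius=100)
        np.testing.assert_array_equal(graph_features(tme), np.zeros(20))

    def test_single_node_only_node_count(self):
        tme = build_pair_graph([_node(0, 0)], [], radius=100)
        vec = graph_features(tme)
        assert vec[F["node_count"]] == 1
        vec[F["node_count"]] = 0
        np.testing.assert_array_equal(vec, np.zeros(20))

    def test_path_of_three_closed_form(self):
        # P3 at unit spacing: Laplacian spectrum {0, 1, 3}, algebraic
        # connectivity 1, MST total length 2, MST diameter 2 edges
        nodes = [_node(0, 0, 1, "a"), _node(1, 0, 2, "b"), _node(2, 0, 1, "c")]
        tme = build_pair_graph(nodes[::2], [nodes[1]], radius=1.0)
        lap = nx.laplacian_matrix(tme.graph, weight=None).toarray()
        np.testing.assert_allclose(np.linalg.eigvalsh(lap), [0.0, 1.0, 3.0], atol=1e-9)
        vec = graph_features(tme)
        assert vec[F["algebraic_connectivity"]] == pytest.approx(1.0)
        assert vec[F["mst_total_length"]] == pytest.approx(2.0)
        assert vec[F["mst_diameter"]] == 2
        assert vec[F["node_count"]] == 3 and vec[F["edge_count"]] == 2
        assert vec[F["cross_class_edge_fraction"]] == pytest.approx(1.0)
        assert vec[F["n_components"]] == 1
        assert vec[F["mean_nn_distance"]] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_mst_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, size=(6, 2))
        nodes = [_node(x, y, 1, f"n{i}") for i, (x, y) in enumerate(pts)]
        tme = build_pair_graph(nodes, [], radius=1e6)  # complete graph
        vec = graph_features(tme)
        assert vec[F["mst_total_length"]] == pytest.approx(exhaustive_mst_length(pts))

    def test_mst_edge_count_per_component(self):
        # two separated pairs: forest has (2-1) + (2-1) = 2 edges
        nodes = [_node(0, 0), _node(10, 0), _node(1000, 0), _node(1010, 0)]
        tme = build_pair_graph(nodes, [], radius=50)
        vec = graph_features(tme)
        assert vec[F["n_components"]] == 2
        assert vec[F["mst_total_length"]] == pytest.approx(20.0)
        assert vec[F["largest_component_fraction"]] == pytest.approx(0.5)

    def test_laplacian_psd_smallest_zero(self):
        rng = np.random.default_rng(7)
        nodes = [_node(x, y, 1, f"n{i}") for i, (x, y) in
                 enumerate(rng.uniform(0, 500, size=(8, 2)))]
        tme = build_pair_graph(nodes, [], radius=300)
        lap = nx.laplacian_matrix(tme.graph, weight=None).toarray()
        eig = np.linalg.eigvalsh(lap)
        assert eig.min() >= -1e-9
        assert abs(eig[0]) < 1e-9

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 500, size=(7, 2))
        nodes = [_node(x, y, 1, f"n{i}") for i, (x, y) in enumerate(pts)]
        moved = [_node(x + 1e4, y - 3e3, 1, f"m{i}") for i, (x, y) in enumerate(pts)]
        a = graph_features(build_pair_graph(nodes, [], radius=250))
        b = graph_features(build_pair_graph(moved, [], radius=250))
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_texture_average_over_interacting_nodes_only(self):
        near = [_node(0, 0, 1, "a"), _node(10, 0, 2, "b")]
        far = _node(1e6, 0, 1, "c")
        for node, val in zip(near + [far], (1.0, 3.0, 99.0)):
            node.mean_texture = np.full(6, val)
        tme = build_pair_graph([near[0], far], [near[1]], radius=100)
        vec = graph_features(tme)
        np.testing.assert_allclose(vec[:6], 2.0)  # isolated node excluded


class TestAllPairs:
    def test_16_classes_give_120_pairs(self):
        assert len(class_pairs()) == 120

    def test_3_classes_give_3_pairs(self):
        assert class_pairs((0, 1, 2)) == [(0, 1), (0, 2), (1, 2)]

    def test_pair_symmetry(self):
        a = [_node(0, 0, 1, "a"), _node(500, 0, 1, "b")]
        b = [_node(200, 0, 2, "c")]
        va = graph_features(build_pair_graph(a, b, radius=400))
        vb = graph_features(build_pair_graph(b, a, radius=400))
        np.testing.assert_allclose(va, vb)

    def test_full_matrix_width(self):
        rng = np.random.default_rng(2)
        grid = rng.integers(0, 16, size=(12, 12))
        vec = all_pair_features(_grid_map(grid))
        assert vec.shape == (120 * 20,)
        assert np.isfinite(vec).all()
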