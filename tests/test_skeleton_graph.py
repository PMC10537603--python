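"""Skeleton-graph morphometry: exact longest simple path, branches, SWC.

Path-search exactness is cross-checked against networkx's independent
simple-path enumeration; branch counts on trees against a recursive
decomposition built on the uniqueness of tree paths.
"""

import networkx as nx
import numpy as np
import pytest

from skelmorph.skeleton_graph import (build_graph, build_graph_from_arrays,
                                      find_branches, longest_simple_path_from,
                                      neuron_length, read_edge_list, read_swc,
                                      write_edge_list, write_swc)


def random_connected_graph(rng, n_nodes, extra_edges):
    """Random connected weighted graph with positions (tree + extra edges)."""
    pos = rng.normal(size=(n_nodes, 3))
    edges = [(int(rng.integers(i)), i) for i in range(1, n_nodes)]
    extra_edges = min(extra_edges,
                      n_nodes * (n_nodes - 1) // 2 - (n_nodes - 1))
    while len(edges) < n_nodes - 1 + extra_edges:
        i, j = rng.integers(n_nodes, size=2)
        if i != j and (min(i, j), max(i, j)) not in edges:
            edges.append((int(min(i, j)), int(max(i, j))))
    return build_graph_from_arrays(pos, np.ones(n_nodes), edges)


def nx_longest_path_length(g):
    """Independent oracle: enumerate all simple paths between all pairs."""
    best = 0.0
    for s in g.nodes:
        for t in g.nodes:
            if s >= t:
                continue
            for path in nx.all_simple_paths(g, s, t):
                w = sum(g[a][b]["weight"] for a, b in zip(path, path[1:]))
                best = max(best, w)
    return best


def tree_branch_count_oracle(g, main_nodes):
    """Independent branch counter for trees: for each main-path node with an
    off-path neighbor, the branch is the farthest-node distance in the
    subtree hanging off it (tree paths are unique, so plain traversal works)."""
    on_path = set(main_nodes)
    B = [b for b in main_nodes
         if any(v not in on_path for v in g.neighbors(b))]
    count = 0
    for b in B:
        sub = g.subgraph(set(g.nodes) - (on_path | set(B)) | {b})
        lengths = nx.single_source_dijkstra_path_length(sub, b)
        if max(lengths.values()) > 0:
            count += 1
    return count


class TestBuildGraph:
    def test_edge_weight_is_center_distance(self):
        g = build_graph_from_arrays(np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                                    np.ones(2), [(0, 1)])
        assert g[0][1]["weight"] == pytest.approx(3.0)

    def test_largest_component_kept(self):
        pos = np.vstack([np.arange(5)[:, None] * [1.0, 0, 0],
                         np.arange(2)[:, None] * [1.0, 0, 0] + [0, 10, 0]])
        g = build_graph_from_arrays(pos, np.ones(7),
                                    [(0, 1), (1, 2), (2, 3), (3, 4), (5, 6)])
        assert g.number_of_nodes() == 5

    def test_cycles_preserved(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [0.5, 1, 0]])
        g = build_graph_from_arrays(pos, np.ones(3), [(0, 1), (1, 2), (0, 2)])
        assert g.number_of_edges() == 3

    def test_coincident_centers_contracted(self):
        pos = np.array([[0.0, 0, 0], [0.0, 0, 0], [1, 0, 0]])
        g = build_graph_from_arrays(pos, np.ones(3), [(0, 1), (1, 2)])
        assert g.number_of_nodes() == 2

    def test_empty_mesh_raises(self):
        from skelmorph.mesh_links import SkeletonMesh
        from skelmorph.skeleton_net import SkeletonSpheres

        mesh = SkeletonMesh(SkeletonSpheres(np.zeros((2, 3)) + [[0], [1]],
                                            np.ones(2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            build_graph(mesh)


class TestLongestPath:
    def test_path_graph_from_end(self):
        g = build_graph_from_arrays(
            np.arange(3)[:, None] * [1.0, 0, 0], np.ones(3), [(0, 1), (1, 2)])
        res = longest_simple_path_from(g, 0)
        assert res.length == pytest.approx(2.0)
        assert res.nodes == [0, 1, 2]

    def test_triangle_cannot_revisit_start(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        g = build_graph_from_arrays(pos, np.ones(3), [(0, 1), (1, 2), (0, 2)])
        res = longest_simple_path_from(g, 0)
        assert len(res.nodes) == 3 and len(set(res.nodes)) == 3

    def test_unknown_node_raises(self):
        g = build_graph_from_arrays(np.zeros((2, 3)) + [[0], [1]],
                                    np.ones(2), [(0, 1)])
        with pytest.raises(KeyError):
            longest_simple_path_from(g, 99)

    def test_exactness_against_nx_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(3, 10))
            g = random_connected_graph(rng, n, int(rng.integers(0, 4)))
            length, path = neuron_length(g)
            assert length == pytest.approx(nx_longest_path_length(g))
            w = sum(g[a][b]["weight"] for a, b in zip(path.nodes,
                                                      path.nodes[1:]))
            assert w == pytest.approx(length)
            assert len(set(path.nodes)) == len(path.nodes)

    def test_invariance_under_relabeling_and_rigid_motion(self):
        rng = np.random.default_rng(3)
        g = random_connected_graph(rng, 8, 3)
        L, _ = neuron_length(g)
        # relabel
        mapping = dict(zip(sorted(g.nodes), rng.permutation(100)[:8]))
        L2, _ = neuron_length(nx.relabel_nodes(g, mapping))
        assert L2 == pytest.approx(L)
        # rigid motion: weights depend only on pairwise distances
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        pos = np.array([g.nodes[n]["position"] for n in sorted(g.nodes)])
        g3 = build_graph_from_arrays(pos @ R.T + 5.0,
                                     np.ones(len(pos)),
                                     [tuple(sorted(e)) for e in g.edges])
        L3, _ = neuron_length(g3)
        assert L3 == pytest.approx(L)

    def test_length_bounds(self):
        rng = np.random.default_rng(9)
        g = random_connected_graph(rng, 7, 2)
        L, _ = neuron_length(g)
        weights = [w for _, _, w in g.edges(data="weight")]
        assert max(weights) <= L <= sum(weights)


class TestBranches:
    def test_path_graph_has_no_branches(self):
        g = build_graph_from_arrays(np.arange(4)[:, None] * [1.0, 0, 0],
                                    np.ones(4), [(0, 1), (1, 2), (2, 3)])
        _, n = find_branches(g)
        assert n == 0

    def test_y_graph_single_branch(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 0]])
        g = build_graph_from_arrays(pos, np.ones(4), [(0, 1), (1, 2), (1, 3)])
        branches, n = find_branches(g)
        assert n == 1
        assert branches[0].length == pytest.approx(1.0)

    def test_star_one_branch_per_branching_node(self):
        # 4 unit arms from a hub: the main path uses two arms; the hub is the
        # single branching node and contributes one branch (its longest
        # remaining arm), regardless of how many arms hang off it
        pos = np.vstack([np.zeros(3), np.eye(3), [0, 0, -1.0]])
        g = build_graph_from_arrays(pos, np.ones(5),
                                    [(0, i) for i in range(1, 5)])
        branches, n = find_branches(g)
        assert n == 1
        assert branches[0].length == pytest.approx(1.0)

    def test_random_trees_match_decomposition_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(100):
            n = int(rng.integers(4, 11))
            g = random_connected_graph(rng, n, 0)
            assert nx.is_tree(g)
            L, main = neuron_length(g)
            _, count = find_branches(g, main)
            assert count == tree_branch_count_oracle(g, main.nodes)


class TestSWC:
    def test_three_row_chain(self, tmp_path):
        p = tmp_path / "chain.swc"
        p.write_text("1 0 0 0 0 0.5 -1\n2 0 1 0 0 0.5 1\n3 0 2 0 0 0.5 2\n")
        g = read_swc(str(p))
        L, _ = neuron_length(g)
        assert L == pytest.approx(2.0)

    def test_round_trip_tree(self, tmp_path):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 0]])
        g = build_graph_from_arrays(pos, np.array([1.0, 2.0, 0.5, 0.3]),
                                    [(0, 1), (1, 2), (1, 3)])
        path = str(tmp_path / "t.swc")
        write_swc(g, path)
        back = read_swc(path)
        assert nx.is_isomorphic(g, back)
        assert (sorted(w for _, _, w in g.edges(data="weight"))
                == pytest.approx(sorted(w for _, _, w in
                                        back.edges(data="weight"))))

    def test_dangling_parent_raises_with_row(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 0 0 0 0 0.5 -1\n2 0 1 0 0 0.5 7\n")
        with pytest.raises(ValueError, match="parent 7"):
            read_swc(str(p))

    def test_cyclic_graph_refuses_swc_but_writes_edge_list(self, tmp_path):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [0.5, 1, 0]])
        g = build_graph_from_arrays(pos, np.ones(3), [(0, 1), (1, 2), (0, 2)])
        with pytest.raises(ValueError):
            write_swc(g, str(tmp_path / "c.swc"))
        path = str(tmp_path / "c.txt")
        write_edge_list(g, path)
        back = read_edge_list(path)
        assert nx.is_isomorphic(g, back)

    def test_malformed_row_raises(self, tmp_path):
        p = tmp_path / "short.swc"
        p.write_text("1 0 0 0\n")
        with pytest.raises(ValueError):
            read_swc(str(p))
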