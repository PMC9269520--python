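"""Skeleton graph topology, adjacency normalization and partitioning."""

import numpy as np
import pytest

from gaitgcn.graph import (
    AdjacencySet,
    SkeletonGraph,
    TopologyError,
    adjacency_from_edges,
    kinect_v2_graph,
    load_graph,
    normalize_adjacency,
    partition_adjacency,
)

from conftest import random_tree


def brute_force_norm(A: np.ndarray) -> np.ndarray:
    """Independent oracle: D̃^(-1/2) (A + I) D̃^(-1/2) written out literally."""
    A_tilde = A + np.eye(A.shape[0])
    D = np.diag(A_tilde.sum(axis=1))
    D_inv_sqrt = np.diag(1.0 / np.sqrt(np.diag(D)))
    return D_inv_sqrt @ A_tilde @ D_inv_sqrt


class TestSkeletonGraph:
    def test_kinect_v2_is_a_25_joint_tree(self, kinect):
        assert kinect.num_joints == 25
        assert len(kinect.edges) == 24
        assert kinect.is_tree()
        assert kinect.joint_names[kinect.center_joint] == "SpineMid"

    def test_parent_map_oriented_toward_center(self, kinect):
        parents = kinect.parent_of
        assert kinect.center_joint not in parents
        assert len(parents) == kinect.num_joints - 1
        # walking up from any joint reaches the center without cycles
        for j in range(kinect.num_joints):
            seen = set()
            while j != kinect.center_joint:
                assert j not in seen
                seen.add(j)
                j = parents[j]

    @pytest.mark.parametrize(
        "edges, err",
        [
            ([(0, 5)], "out of range"),
            ([(1, 1)], "self-loop"),
            ([(0, 1), (1, 0)], "duplicate"),
        ],
    )
    def test_invalid_topologies_rejected(self, edges, err):
        with pytest.raises(TopologyError, match=err):
            SkeletonGraph(num_joints=3, edges=tuple(edges), center_joint=0)

    def test_hop_distances_by_bfs(self, kinect):
        dist = kinect.hop_distances()
        assert dist[kinect.center_joint] == 0
        # SpineMid(1) - SpineBase(0) - HipLeft(12) - KneeLeft(13)
        assert dist[0] == 1 and dist[12] == 2 and dist[13] == 3


class TestAdjacency:
    def test_single_edge_pair(self):
        g = SkeletonGraph(num_joints=2, edges=((0, 1),), center_joint=0)
        assert np.array_equal(
            adjacency_from_edges(g), [[0.0, 1.0], [1.0, 0.0]]
        )

    def test_edgeless_graph_is_zero(self):
        g = SkeletonGraph(num_joints=3, edges=(), center_joint=0)
        assert np.array_equal(adjacency_from_edges(g), np.zeros((3, 3)))

    def test_kinect_tree_has_48_nonzeros(self, kinect):
        A = adjacency_from_edges(kinect)
        assert (A > 0).sum() == 48  # 2 (V - 1) for a symmetric tree
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)


class TestNormalizeAdjacency:
    def test_single_node(self):
        assert np.allclose(normalize_adjacency(np.zeros((1, 1))), [[1.0]])

    def test_two_node_closed_form(self):
        out = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(out, 0.5)

    def test_three_node_path_matches_oracle(self):
        A = np.array(
            [[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]
        )
        out = normalize_adjacency(A)
        assert np.abs(out - brute_force_norm(A)).max() <= 1e-12
        # degrees 2, 3, 2 → entry (0,1) = 1/sqrt(6)
        assert out[0, 1] == pytest.approx(1.0 / np.sqrt(6.0), abs=1e-12)

    def test_random_graphs_match_oracle(self, rng):
        for _ in range(100):
            V = int(rng.integers(1, 26))
            A = (rng.random((V, V)) < 0.3).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            out = normalize_adjacency(A)
            assert np.abs(out - brute_force_norm(A)).max() <= 1e-10
            assert np.abs(out - out.T).max() <= 1e-12
            assert out.min() >= 0.0 and out.max() <= 1.0 + 1e-12
            top = np.linalg.eigvalsh(out).max()
            assert abs(top - 1.0) <= 1e-9

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestPartitionAdjacency:
    def test_uni_label_equals_full_normalization(self, kinect):
        adj = partition_adjacency(kinect, "uni-label")
        assert adj.num_partitions == 1
        A = adjacency_from_edges(kinect)
        assert np.allclose(adj.partitions[0], normalize_adjacency(A))

    def test_distance_strategy_splits_self_and_neighbors(self, kinect):
        adj = partition_adjacency(kinect, "distance")
        assert adj.num_partitions == 2
        assert np.all((adj.partitions[0] > 0) == np.eye(25, dtype=bool))
        assert np.all(np.diag(adj.partitions[1]) == 0)

    def test_spatial_configuration_on_three_chain(self):
        # chain 0-1-2 with center 0: BFS hops are (0, 1, 2)
        g = SkeletonGraph(
            num_joints=3, edges=((0, 1), (1, 2)), center_joint=0
        )
        adj = partition_adjacency(g, "spatial-configuration")
        self_p, centri, centrifu = adj.partitions
        assert np.all((self_p > 0) == np.eye(3, dtype=bool))
        # target 1 ← source 2 (hop 2 > hop 1): centrifugal
        assert centrifu[1, 2] > 0 and centri[1, 2] == 0
        # target 2 ← source 1 (hop 1 < hop 2): centripetal
        assert centri[2, 1] > 0 and centrifu[2, 1] == 0

    @pytest.mark.parametrize(
        "strategy", ["uni-label", "distance", "spatial-configuration"]
    )
    def test_support_conservation_on_random_trees(self, strategy, rng):
        for _ in range(50):
            V = int(rng.integers(2, 26))
            g = random_tree(rng, V)
            adj = partition_adjacency(g, strategy)
            A_tilde_support = (
                adjacency_from_edges(g) + np.eye(V)
            ) > 0
            claimed = np.zeros((V, V), dtype=int)
            for part in adj.partitions:
                claimed += (part > 0).astype(int)
            assert np.array_equal(claimed > 0, A_tilde_support)
            assert claimed.max() <= 1  # no connection claimed twice

    def test_partitions_nonnegative(self, kinect):
        adj = partition_adjacency(kinect)
        for part in adj.partitions:
            assert part.min() >= 0.0

    def test_permutation_equivariance(self, rng, kinect):
        A = adjacency_from_edges(kinect)
        out = normalize_adjacency(A)
        for _ in range(5):
            perm = rng.permutation(25)
            P = np.eye(25)[perm]
            permuted = normalize_adjacency(A[np.ix_(perm, perm)])
            assert np.abs(permuted - P @ out @ P.T).max() <= 1e-12

    def test_unknown_strategy_rejected(self, kinect):
        with pytest.raises(ValueError, match="unknown partition strategy"):
            partition_adjacency(kinect, "parts")


class TestGraphFile:
    def test_round_trip_edge_list(self, tmp_path, kinect):
        path = tmp_path / "graph.txt"
        lines = [f"V={kinect.num_joints} center={kinect.center_joint}"]
        lines += [f"{i} {j}" for i, j in kinect.edges]
        path.write_text("\n".join(lines))
        g = load_graph(path)
        assert g.num_joints == 25
        assert set(map(frozenset, g.edges)) == set(
            map(frozenset, kinect.edges)
        )
        assert g.center_joint == kinect.center_joint

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("25 joints\n0 1\n")
        with pytest.raises(TopologyError, match="header"):
            load_graph(path)
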