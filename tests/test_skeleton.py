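"""Topology validation, adjacency partitioning/normalization and motion
preprocessing (downsampling, quantile binning), plus the file formats."""

import json

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import normalize_adjacency_loops
from stagcn.skeleton import (
    LabeledSample,
    MotionSequence,
    SkeletonTopology,
    build_partition,
    downsample,
    load_dataset_h5,
    load_motion_csv,
    load_topology,
    normalize_adjacency,
    quartile_bin,
    save_dataset_h5,
    save_motion_csv,
    save_topology,
    quartile_bin as qbin,
)


def chain(n, root=1):
    return SkeletonTopology(n, tuple(f"j{i}" for i in range(n)),
                            tuple((i, i + 1) for i in range(1, n)), root)


class TestTopology:
    def test_rejects_bad_edges(self):
        with pytest.raises(ValueError, match="self-loop"):
            SkeletonTopology(2, ("a", "b"), ((1, 1),))
        with pytest.raises(ValueError, match="duplicate"):
            SkeletonTopology(2, ("a", "b"), ((1, 2), (2, 1)))
        with pytest.raises(ValueError, match="out of"):
            SkeletonTopology(2, ("a", "b"), ((1, 3),))

    def test_disconnected_graph_warns_not_errors(self):
        with pytest.warns(UserWarning, match="not connected"):
            SkeletonTopology(3, ("a", "b", "c"), ((1, 2),))

    def test_json_round_trip(self, tmp_path):
        topo = chain(4, root=2)
        path = tmp_path / "topo.json"
        save_topology(topo, path)
        assert json.loads(path.read_text())["root"] == 2
        assert load_topology(path) == topo


class TestPartition:
    def test_two_joint_chain_spatial(self):
        part = build_partition(chain(2), "spatial")
        assert part.n_partitions == 3
        np.testing.assert_array_equal(part.matrices[0], np.eye(2))
        np.testing.assert_array_equal(part.matrices[1], [[0, 0], [1, 0]])
        np.testing.assert_array_equal(part.matrices[2], [[0, 1], [0, 0]])

    def test_uni_is_plain_adjacency(self):
        topo = chain(4)
        part = build_partition(topo, "uni")
        assert part.n_partitions == 1
        np.testing.assert_array_equal(part.matrices[0], topo.adjacency())

    def test_distance_splits_self_and_neighbours(self):
        part = build_partition(chain(3), "distance")
        np.testing.assert_array_equal(part.matrices[0], np.eye(3))
        np.testing.assert_array_equal(part.matrices[1], chain(3).adjacency())

    def test_star_matches_bfs_oracle(self):
        """Spatial partition of a 5-joint star equals a brute-force
        hop-distance classification of every directed edge."""
        star = SkeletonTopology(5, tuple("abcde"), ((1, 2), (1, 3), (1, 4), (1, 5)))
        part = build_partition(star, "spatial")
        g = star.graph()
        dist = nx.single_source_shortest_path_length(g, 0)
        expect = np.zeros((3, 5, 5))
        expect[0] = np.eye(5)
        for i, j in g.edges:
            for a, b in ((i, j), (j, i)):
                h = 1 if dist[b] < dist[a] else 2
                expect[h, a, b] = 1.0
        np.testing.assert_array_equal(part.matrices, expect)

    def test_every_edge_covered_exactly_once(self):
        topo = chain(6, root=3)
        for strategy in ("uni", "distance", "spatial"):
            part = build_partition(topo, strategy)
            support = (part.matrices.sum(axis=0) > 0).astype(float)
            off_diag = support - np.diag(np.diag(support))
            np.testing.assert_array_equal(off_diag, topo.adjacency())
            # each directed intra-body edge appears in exactly one partition
            counts = part.matrices.sum(axis=0)[topo.adjacency() > 0]
            np.testing.assert_array_equal(counts, np.ones_like(counts))

    def test_unknown_strategy_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            build_partition(chain(2), "fancy")

    def test_disconnected_root_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            topo = SkeletonTopology(4, tuple("abcd"), ((1, 2), (3, 4)))
            part = build_partition(topo, "spatial")
        # the disconnected pair lands in the neighbour (centripetal) class
        assert part.matrices[1, 2, 3] == 1.0 and part.matrices[1, 3, 2] == 1.0


class TestNormalizeAdjacency:
    def test_zero_matrix_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((3, 3))), np.eye(3))

    def test_two_node_hand_value(self):
        out = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(out, np.full((2, 2), 0.5))

    @given(st.integers(2, 8), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_scalar_oracle_on_random_graphs(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=(n, n)).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        np.testing.assert_allclose(
            normalize_adjacency(a), normalize_adjacency_loops(a), atol=1e-10
        )

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.array([[0.0, -1.0], [-1.0, 0.0]]))


def seq(f, n=2, c=3):
    return MotionSequence(np.arange(f * n * c, dtype=float).reshape(f, n, c))


class TestDownsample:
    def test_regular_spacing_keeps_endpoints(self):
        out = downsample(seq(9), 3)
        np.testing.assert_array_equal(out.data, seq(9).data[[0, 4, 8]])

    def test_same_length_is_identity(self):
        np.testing.assert_array_equal(downsample(seq(5), 5).data, seq(5).data)

    def test_matches_rounded_linspace_and_gap_property(self):
        out = downsample(seq(100), 32)
        idx = np.floor(np.linspace(0, 99, 32) + 0.5).astype(int)
        np.testing.assert_array_equal(out.data, seq(100).data[idx])
        gaps = np.diff(idx)
        assert np.all(gaps > 0) and gaps.max() - gaps.min() <= 1

    def test_idempotent_at_same_target(self):
        once = downsample(seq(50), 7)
        np.testing.assert_array_equal(downsample(once, 7).data, once.data)

    def test_invalid_targets_error(self):
        with pytest.raises(ValueError):
            downsample(seq(5), 6)
        with pytest.raises(ValueError):
            downsample(seq(5), 1)


class TestQuartileBin:
    @pytest.mark.parametrize(
        "scores,m,expected",
        [
            ((1, 2, 3, 4), 4, (1, 2, 3, 4)),
            ((10, 10, 20, 20, 30, 30, 40, 40), 4, (1, 1, 2, 2, 3, 3, 4, 4)),
            ((1, 2, 3, 4), 2, (1, 1, 2, 2)),
        ],
    )
    def test_examples(self, scores, m, expected):
        np.testing.assert_array_equal(quartile_bin(scores, m), expected)

    def test_boundary_tie_goes_to_lower_class(self):
        # the median of (1,3,3,5) is exactly 3: scores on the cut stay low
        np.testing.assert_array_equal(qbin((1.0, 3.0, 3.0, 5.0), 2), (1, 1, 1, 2))

    def test_balanced_sizes_for_distinct_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.permutation(np.linspace(0, 1, 40))
        counts = np.bincount(quartile_bin(scores, 4))[1:]
        assert counts.max() - counts.min() <= 1

    def test_degenerate_scores_error(self):
        with pytest.raises(ValueError):
            quartile_bin([5.0, 5.0, 5.0, 5.0], 4)


class TestMotionIO:
    def test_csv_round_trip(self, tmp_path):
        s = seq(6, n=3, c=2)
        path = tmp_path / "m.csv"
        save_motion_csv(s, path)
        back = load_motion_csv(path, n_joints=3, n_channels=2)
        np.testing.assert_allclose(back.data, s.data)

    def test_h5_round_trip_preserves_labels_and_split(self, tmp_path):
        samples = [
            LabeledSample(seq(4), label=2, score=1.5, split="test", sample_id="a"),
            LabeledSample(seq(5), label=4, split="train", sample_id="b"),
        ]
        path = tmp_path / "d.h5"
        save_dataset_h5(samples, path)
        back = load_dataset_h5(path)
        assert [s.label for s in back] == [2, 4]
        assert [s.split for s in back] == ["test", "train"]
        assert back[0].score == pytest.approx(1.5)
        np.testing.assert_allclose(back[1].sequence.data, samples[1].sequence.data)

    def test_non_finite_motion_rejected(self):
        with pytest.raises(ValueError):
            MotionSequence(np.full((2, 2, 3), np.nan))
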