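import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from knng import (
    METRICS,
    ChunkBufferRecorder,
    ExpressionMatrix,
    KnnGraph,
    MetricSpec,
    NeighborList,
    brute_force_knn,
    build_knn_graph,
    compute_distance_chunk,
    generate_fixture,
    plan,
    query_neighbors,
    update_topk,
)
from knng.metrics import MAX_DISTANCE


def edge_sets(graph: KnnGraph):
    return {
        s: set(graph.targets[s * graph.k : (s + 1) * graph.k].tolist())
        for s in range(graph.n_points)
    }


class TestNeighborList:
    def test_hand_worked_top2_with_self_skip(self):
        # distances from point 0 to points 0..3: [self, 0.5, 0.2, 0.9]
        nl = NeighborList(point_index=0, k=2)
        for j, w in enumerate([0.0, 0.5, 0.2, 0.9]):
            nl.offer(j, w)
        assert nl.topk() == [(2, 0.2), (1, 0.5)]
        assert nl.weights[nl.maxk_pos] == 0.5

    def test_equal_candidate_does_not_replace(self):
        nl = NeighborList(point_index=9, k=1)
        nl.offer(1, 0.5)
        assert not nl.offer(2, 0.5)  # strict <; smaller index kept
        assert nl.topk() == [(1, 0.5)]

    @given(
        weights=st.lists(
            st.floats(min_value=0, max_value=10, allow_nan=False),
            min_size=1,
            max_size=30,
        ),
        k=st.integers(1, 6),
    )
    def test_streaming_equals_lexicographic_selection(self, weights, k):
        """The Maxk replace-then-rescan update keeps exactly the k best
        candidates under the (weight, index) order."""
        nl = NeighborList(point_index=-1, k=k)
        for j, w in enumerate(weights):
            nl.offer(j, w)
        order = np.lexsort((np.arange(len(weights)), np.asarray(weights)))
        expected = [(int(j), float(weights[j])) for j in order[:k]]
        got = [e for e in nl.topk() if e[0] >= 0]
        assert got == expected


class TestComputeDistanceChunk:
    def setup_method(self):
        self.m = generate_fixture(10, 6, n_blocks=2, noise_sd=0.5, seed=2)
        self.geom = plan(10, 6, chunk_size_nc=4, block_size_b=2)
        self.spec = MetricSpec("euclidean", block_size_b=2)

    def test_diagonal_chunk_has_zero_self_distances(self):
        tile = compute_distance_chunk(self.m, self.geom.position(0, 0), self.geom, self.spec)
        np.testing.assert_allclose(np.diag(tile), 0, atol=1e-12)

    def test_off_diagonal_chunks_are_transposes(self):
        t01 = compute_distance_chunk(self.m, self.geom.position(0, 1), self.geom, self.spec)
        t10 = compute_distance_chunk(self.m, self.geom.position(1, 0), self.geom, self.spec)
        np.testing.assert_allclose(t01, t10.T, rtol=1e-12)

    def test_pad_entries_carry_sentinel(self):
        # 10 points, chunk 4: chunk (2,2) covers rows/cols 8..11; 10, 11 pad
        tile = compute_distance_chunk(self.m, self.geom.position(2, 2), self.geom, self.spec)
        assert (tile[2:, :] == MAX_DISTANCE).all()
        assert (tile[:, 2:] == MAX_DISTANCE).all()
        expected = np.array(
            [
                [0.0, np.linalg.norm(self.m.values[8] - self.m.values[9])],
                [np.linalg.norm(self.m.values[9] - self.m.values[8]), 0.0],
            ]
        )
        np.testing.assert_allclose(tile[:2, :2], expected, rtol=1e-10)

    def test_recorder_counts_one_tile(self):
        rec = ChunkBufferRecorder()
        compute_distance_chunk(
            self.m, self.geom.position(0, 0), self.geom, self.spec, recorder=rec
        )
        assert rec.allocations == [16]


class TestUpdateTopk:
    def _state(self, nc, k):
        return (
            np.full((nc, k), -1, dtype=np.int64),
            np.full((nc, k), np.inf, dtype=np.float64),
        )

    def test_hand_worked_diagonal_row(self):
        geom = plan(4, 2, chunk_size_nc=4, block_size_b=2)
        pos = geom.position(0, 0)
        chunk = np.full((4, 4), MAX_DISTANCE)
        chunk[0] = [0.0, 0.5, 0.2, 0.9]
        state = self._state(4, 2)
        update_topk(state, chunk, pos, k=2)
        idx, w = state
        assert sorted(zip(idx[0], w[0])) == [(1, 0.5), (2, 0.2)]
        # stored in ascending (weight, index) order
        assert list(idx[0]) == [2, 1] and list(w[0]) == [0.2, 0.5]

    def test_all_pad_chunk_leaves_state_unchanged(self):
        from knng import ChunkPosition

        all_pad = ChunkPosition(
            split_index=0,
            chunk_index=2,
            row_offset=0,
            col_offset=8,
            is_diagonal=False,
            pad_rows=0,
            pad_cols=4,
        )
        state = self._state(4, 2)
        before = (state[0].copy(), state[1].copy())
        update_topk(state, np.full((4, 4), MAX_DISTANCE), all_pad, k=2)
        np.testing.assert_array_equal(state[0], before[0])
        np.testing.assert_array_equal(state[1], before[1])

    def test_processing_same_chunk_twice_is_idempotent(self, rng):
        m = rng.standard_normal((8, 5))
        geom = plan(8, 5, chunk_size_nc=4, block_size_b=1)
        spec = MetricSpec("euclidean", 1)
        pos = geom.position(0, 0)
        tile = compute_distance_chunk(m, pos, geom, spec)
        once = self._state(4, 3)
        update_topk(once, tile, pos, k=3)
        twice = (once[0].copy(), once[1].copy())
        update_topk(twice, tile, pos, k=3)
        np.testing.assert_array_equal(once[0], twice[0])
        np.testing.assert_array_equal(once[1], twice[1])


class TestBuildKnnGraph:
    def test_four_point_line_k1(self, line_matrix):
        g = build_knn_graph(
            line_matrix, k=1, metric="euclidean", chunk_size_nc=2, block_size_b=1
        )
        assert g.edges() == [(0, 1, 1.0), (1, 0, 1.0), (2, 1, 2.0), (3, 2, 4.0)]

    def test_brute_force_matches_line_example(self, line_matrix):
        g = brute_force_knn(line_matrix, k=1, metric="euclidean")
        assert g.edges() == [(0, 1, 1.0), (1, 0, 1.0), (2, 1, 2.0), (3, 2, 4.0)]

    @pytest.mark.parametrize("metric", METRICS)
    @pytest.mark.parametrize("nc, segments", [(16, 1), (64, 2), (160, 3)])
    def test_oracle_equivalence_across_chunkings(
        self, small_fixture, metric, nc, segments
    ):
        spec = MetricSpec(metric, block_size_b=16)
        ref = brute_force_knn(small_fixture, k=10, metric=spec)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            g = build_knn_graph(
                small_fixture,
                k=10,
                metric=spec,
                chunk_size_nc=nc,
                block_size_b=16,
                n_segments=segments,
            )
        np.testing.assert_array_equal(g.targets, ref.targets)
        np.testing.assert_array_equal(g.sources, ref.sources)
        np.testing.assert_allclose(g.weights, ref.weights, rtol=1e-12, atol=0)

    def test_k_equals_n_minus_1_connects_everything(self, rng):
        X = rng.standard_normal((9, 4))
        g = build_knn_graph(X, k=8, metric="manhattan", chunk_size_nc=4, block_size_b=2)
        for s, nbrs in edge_sets(g).items():
            assert nbrs == set(range(9)) - {s}

    def test_coincident_points_have_zero_weight_edges(self):
        m = ExpressionMatrix(
            np.array([[1.0, 2.0], [1.0, 2.0], [50.0, -3.0]]),
            ["a", "b", "far"],
            ["x", "y"],
        )
        g = brute_force_knn(m, k=1, metric="euclidean")
        assert g.edges()[0] == (0, 1, 0.0)
        assert g.edges()[1] == (1, 0, 0.0)

    def test_zero_noise_blocks_give_zero_pearson_weights(self):
        m = generate_fixture(10, 5, n_blocks=2, noise_sd=0.0, seed=1)
        g = brute_force_knn(m, k=1, metric="pearson")
        from knng.matrix_io import fixture_block_labels

        labels = fixture_block_labels(10, 2)
        assert (labels[g.sources] == labels[g.targets]).all()
        np.testing.assert_allclose(g.weights, 0, atol=1e-12)

    @pytest.mark.parametrize("k", [0, 150, 200])
    def test_invalid_k_rejected(self, small_fixture, k):
        with pytest.raises(ValueError):
            build_knn_graph(small_fixture, k=k)
        with pytest.raises(ValueError):
            brute_force_knn(small_fixture, k=k)

    def test_graph_invariants(self, small_fixture):
        g = build_knn_graph(
            small_fixture, k=7, metric="pearson", chunk_size_nc=32, block_size_b=16
        )
        assert g.n_edges == 7 * 150
        assert (g.sources != g.targets).all()
        assert (g.targets >= 0).all() and (g.targets < 150).all()
        for s, nbrs in edge_sets(g).items():
            assert len(nbrs) == 7
        # per-source weights non-decreasing
        w = g.weights.reshape(150, 7)
        assert (np.diff(w, axis=1) >= 0).all()

    def test_neighbour_sets_nest_as_k_grows(self, small_fixture):
        g5 = brute_force_knn(small_fixture, k=5, metric="pearson")
        g6 = brute_force_knn(small_fixture, k=6, metric="pearson")
        e5, e6 = edge_sets(g5), edge_sets(g6)
        assert all(e5[s] <= e6[s] for s in e5)

    def test_peak_distance_storage_is_one_chunk(self):
        m = generate_fixture(200, 10, n_blocks=5, noise_sd=0.2, seed=9)
        rec = ChunkBufferRecorder()
        build_knn_graph(
            m,
            k=5,
            metric="pearson",
            chunk_size_nc=32,
            block_size_b=16,
            recorder=rec,
        )
        assert rec.max_entries == 32 * 32
        assert len(rec.allocations) == 7 * 7  # ceil(200/32)^2 chunks
        assert all(a <= 32 * 32 for a in rec.allocations)

    def test_agrees_with_sklearn_nearest_neighbors(self, rng):
        """Independent cross-check against sklearn's exhaustive kNN."""
        from sklearn.neighbors import NearestNeighbors

        X = rng.standard_normal((80, 9))
        for ours, theirs in [
            ("euclidean", "euclidean"),
            ("manhattan", "manhattan"),
            ("pearson", "correlation"),
        ]:
            g = build_knn_graph(
                X, k=4, metric=ours, chunk_size_nc=16, block_size_b=1
            )
            nn = NearestNeighbors(n_neighbors=5, metric=theirs, algorithm="brute")
            nn.fit(X)
            dist, ind = nn.kneighbors(X)
            got = edge_sets(g)
            for s in range(80):
                keep = ind[s] != s  # sklearn reports the point itself
                assert got[s] == set(ind[s][keep][:4].tolist())
                np.testing.assert_allclose(
                    g.weights[s * 4 : (s + 1) * 4],
                    dist[s][keep][:4],
                    rtol=1e-8,
                    atol=1e-10,
                )


class TestQueryNeighbors:
    def test_query_by_id_returns_ordered_pairs(self, line_matrix):
        g = build_knn_graph(
            line_matrix, k=2, metric="euclidean", chunk_size_nc=2, block_size_b=1
        )
        assert query_neighbors(g, "d") == [("c", 4.0), ("b", 6.0)]
        assert query_neighbors(g, 3) == [("c", 4.0), ("b", 6.0)]

    def test_unknown_id_raises_lookup_error(self, line_matrix):
        g = brute_force_knn(line_matrix, k=1, metric="euclidean")
        with pytest.raises(LookupError):
            query_neighbors(g, "nope")
        with pytest.raises(LookupError):
            query_neighbors(g, 42)

    def test_every_query_returns_k_nondecreasing_weights(self, small_fixture):
        g = brute_force_knn(small_fixture, k=6, metric="spearman")
        for key in (0, 17, 149):
            pairs = query_neighbors(g, key)
            assert len(pairs) == 6
            weights = [w for _, w in pairs]
            assert weights == sorted(weights)
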