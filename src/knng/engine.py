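"""Chunked exact kNN-graph construction.

The engine walks the virtual distance matrix one square chunk at a time:
a distance kernel fills an ``n_c x n_c`` tile, then a streaming top-k
update folds the tile's columns into per-row neighbour buffers.  When
every chunk of a split has been seen, the neighbour lists of that row
band are final and are emitted as directed, weighted edges.  Peak
distance storage is therefore one chunk (n_c^2 entries) per worker, never
the full n^2 matrix.

Tie rule (shared with :func:`brute_force_knn`, the exhaustive oracle): a
candidate replaces the current farthest entry only when strictly closer;
among equal final distances at the k-th position the smaller global index
wins.  The rule makes the output identical for every chunk size and
segment count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.stats import rankdata

from .chunking import ChunkGeometry, ChunkPosition, plan
from .matrix_io import ExpressionMatrix
from .metrics import MAX_DISTANCE, MetricSpec, distance_block

__all__ = [
    "NeighborList",
    "KnnGraph",
    "ChunkBufferRecorder",
    "compute_distance_chunk",
    "update_topk",
    "build_knn_graph",
    "brute_force_knn",
    "query_neighbors",
]


class ChunkBufferRecorder:
    """Records every distance-tile allocation (entry counts).

    Lets callers verify that a build never holds more than one
    chunk-sized distance buffer at a time.
    """

    def __init__(self) -> None:
        self.allocations: list[int] = []

    def record(self, n_entries: int) -> None:
        self.allocations.append(int(n_entries))

    @property
    def max_entries(self) -> int:
        return max(self.allocations, default=0)


class NeighborList:
    """Running k-best buffer for one point, with a farthest-entry locator.

    Mirrors a fixed-size neighbour array plus a ``maxk`` pointer: a
    candidate is compared against the entry at ``maxk_pos`` and replaces
    it when strictly closer, after which the farthest position is
    re-located by a linear scan.  Empty slots hold index -1 and weight
    +inf.  Among slots tied at the maximum weight the scan prefers the
    largest neighbour index, so the buffer always equals the k best
    candidates seen so far under the (weight, index) lexicographic order.
    """

    __slots__ = ("point_index", "k", "indices", "weights", "maxk_pos")

    def __init__(self, point_index: int, k: int) -> None:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        self.point_index = int(point_index)
        self.k = int(k)
        self.indices = np.full(k, -1, dtype=np.int64)
        self.weights = np.full(k, np.inf, dtype=np.float64)
        self.maxk_pos = 0

    def _rescan(self) -> None:
        w = self.weights
        best = 0
        for pos in range(1, self.k):
            if w[pos] > w[best] or (
                w[pos] == w[best] and self.indices[pos] > self.indices[best]
            ):
                best = pos
        self.maxk_pos = best

    def offer(self, neighbor_index: int, weight: float) -> bool:
        """Offer one candidate; returns True if it entered the buffer."""
        if neighbor_index == self.point_index:
            return False
        if weight < self.weights[self.maxk_pos]:
            self.weights[self.maxk_pos] = weight
            self.indices[self.maxk_pos] = neighbor_index
            self._rescan()
            return True
        return False

    def topk(self) -> list[tuple[int, float]]:
        """Entries sorted by (weight, index)."""
        order = np.lexsort((self.indices, self.weights))
        return [
            (int(self.indices[pos]), float(self.weights[pos])) for pos in order
        ]


@dataclass
class KnnGraph:
    """Directed kNN graph as flat parallel edge arrays.

    Exactly k edges per source, stored contiguously by source index and,
    within a source, by ascending (weight, target).
    """

    sources: np.ndarray
    targets: np.ndarray
    weights: np.ndarray
    k: int
    n_points: int
    metric: MetricSpec
    row_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=np.int64)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n_edges = self.k * self.n_points
        if not (
            self.sources.shape == self.targets.shape == self.weights.shape
            and self.sources.size == n_edges
        ):
            raise ValueError(
                f"expected {n_edges} edges, got "
                f"{self.sources.size}/{self.targets.size}/{self.weights.size}"
            )
        if self.row_ids is not None and len(self.row_ids) != self.n_points:
            raise ValueError("row_ids length does not match n_points")

    @property
    def n_edges(self) -> int:
        return self.sources.size

    def edges(self) -> list[tuple[int, int, float]]:
        return list(
            zip(
                self.sources.tolist(),
                self.targets.tolist(),
                self.weights.tolist(),
            )
        )

    def neighbors_of(self, source_index: int) -> list[tuple[int, float]]:
        if not 0 <= source_index < self.n_points:
            raise LookupError(f"source index {source_index} out of range")
        lo = source_index * self.k
        sl = slice(lo, lo + self.k)
        return list(
            zip(self.targets[sl].tolist(), self.weights[sl].tolist())
        )

    def to_dataframe(self):
        import pandas as pd

        if self.row_ids is not None:
            ids = np.asarray(self.row_ids, dtype=object)
            return pd.DataFrame(
                {
                    "source": ids[self.sources],
                    "target": ids[self.targets],
                    "weight": self.weights,
                }
            )
        return pd.DataFrame(
            {"source": self.sources, "target": self.targets, "weight": self.weights}
        )

    def to_sparse(self) -> csr_matrix:
        """Sparse n x n matrix with entry (i, j) = distance for edge i->j."""
        return csr_matrix(
            (self.weights, (self.sources, self.targets)),
            shape=(self.n_points, self.n_points),
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        if self.row_ids is not None:
            g.add_nodes_from(self.row_ids)
            frame = self.to_dataframe()
            g.add_weighted_edges_from(
                frame.itertuples(index=False, name=None)
            )
        else:
            g.add_nodes_from(range(self.n_points))
            g.add_weighted_edges_from(self.edges())
        return g

    def write_edges(self, path, delimiter: str = "\t") -> None:
        """Write the edge list (source, target, weight), one edge per line."""
        self.to_dataframe().to_csv(
            path, sep=delimiter, header=False, index=False
        )

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def _values_of(matrix) -> np.ndarray:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return np.atleast_2d(np.asarray(matrix, dtype=np.float64))


def _row_ids_of(matrix) -> list[str] | None:
    if isinstance(matrix, ExpressionMatrix):
        return list(matrix.row_ids)
    return None


def compute_distance_chunk(
    matrix,
    pos: ChunkPosition,
    geom: ChunkGeometry,
    metric="pearson",
    recorder: ChunkBufferRecorder | None = None,
) -> np.ndarray:
    """Fill one n_c x n_c tile of the virtual distance matrix.

    Entry (i, j) is the distance between global points
    ``row_offset + i`` and ``col_offset + j``; entries whose row or
    column falls in the pad region carry the sentinel ``MAX_DISTANCE``.
    """
    spec = metric if isinstance(metric, MetricSpec) else MetricSpec(
        name=str(metric), block_size_b=geom.block_size_b
    )
    values = _values_of(matrix)
    nc = geom.chunk_size_nc
    tile = np.full((nc, nc), MAX_DISTANCE, dtype=np.float64)
    if recorder is not None:
        recorder.record(tile.size)
    n_rows = nc - pos.pad_rows
    n_cols = nc - pos.pad_cols
    if n_rows > 0 and n_cols > 0:
        rows = values[pos.row_offset : pos.row_offset + n_rows]
        cols = values[pos.col_offset : pos.col_offset + n_cols]
        tile[:n_rows, :n_cols] = distance_block(rows, cols, spec)
    return tile


def update_topk(
    state: tuple[np.ndarray, np.ndarray],
    chunk: np.ndarray,
    pos: ChunkPosition,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fold one chunk into the neighbour buffers of its split, in place.

    ``state`` is a pair of (n_c, k) arrays — neighbour indices (-1 for
    empty) and weights (+inf for empty) — for the rows
    ``row_offset .. row_offset + n_c - 1``.  For every valid row, each
    valid chunk column (not past ``n_points``, not the row's own point)
    is merged into the row's k-best set under the (weight, index)
    lexicographic order; exact duplicate candidates are dropped, making
    the operation idempotent.  Rows and columns in the pad region are
    skipped.
    """
    nbr_idx, nbr_w = state
    nc = chunk.shape[0]
    n_rows = nc - pos.pad_rows
    n_cols = nc - pos.pad_cols
    if n_rows <= 0 or n_cols <= 0:
        return state
    global_cols = pos.col_offset + np.arange(n_cols, dtype=np.int64)
    for r in range(n_rows):
        point = pos.row_offset + r
        cand_w = chunk[r, :n_cols]
        cand_i = global_cols
        if pos.is_diagonal:
            keep = cand_i != point
            cand_w = cand_w[keep]
            cand_i = cand_i[keep]
        merged_w = np.concatenate((nbr_w[r], cand_w))
        merged_i = np.concatenate((nbr_idx[r], cand_i))
        order = np.lexsort((merged_i, merged_w))
        mi = merged_i[order]
        mw = merged_w[order]
        # identical (index, weight) pairs sort adjacently; drop repeats of
        # real indices so re-offering a seen candidate cannot double it
        dup = np.zeros(mi.size, dtype=bool)
        dup[1:] = (mi[1:] == mi[:-1]) & (mw[1:] == mw[:-1]) & (mi[1:] >= 0)
        mi = mi[~dup]
        mw = mw[~dup]
        nbr_idx[r, :] = mi[:k]
        nbr_w[r, :] = mw[:k]
    return state


def _effective(values: np.ndarray, spec: MetricSpec) -> tuple[np.ndarray, MetricSpec]:
    """Spearman is Pearson on row ranks; rank once up front."""
    if spec.name == "spearman":
        return (
            rankdata(values, axis=1),
            MetricSpec(name="pearson", block_size_b=spec.block_size_b),
        )
    return values, spec


def _validate_k(k: int, n_points: int) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= n_points:
        raise ValueError(
            f"k must be <= n_points - 1 = {n_points - 1}, got {k}"
        )


def build_knn_graph(
    matrix,
    k: int,
    metric="pearson",
    chunk_size_nc: int = 1024,
    block_size_b: int = 16,
    n_segments: int = 1,
    recorder: ChunkBufferRecorder | None = None,
    logger=None,
) -> KnnGraph:
    """Exact kNN graph via chunked distance evaluation.

    The output is identical for every valid chunk size and segment
    count; only the work partition changes.  Segments own whole splits
    and are processed independently; their partial graphs are
    concatenated by source row.
    """
    values = _values_of(matrix)
    n_points, n_dims = values.shape
    _validate_k(k, n_points)
    spec = metric if isinstance(metric, MetricSpec) else MetricSpec(
        name=str(metric), block_size_b=block_size_b
    )
    geom = plan(n_points, n_dims, chunk_size_nc, block_size_b, n_segments)
    if logger is not None:
        logger.info(
            "geometry: %d points padded to M=%d, %d dims padded to N=%d; "
            "%d splits x %d chunks, %d segment(s)",
            n_points,
            geom.padded_points_M,
            n_dims,
            geom.padded_dims_N,
            geom.n_splits,
            geom.n_chunks_per_split,
            geom.n_segments,
        )
    work, eff_spec = _effective(values, spec)

    targets = np.empty(n_points * k, dtype=np.int64)
    weights = np.empty(n_points * k, dtype=np.float64)
    nc = geom.chunk_size_nc
    for segment in range(geom.n_segments):
        splits = geom.segment_splits(segment)
        if logger is not None:
            logger.info("segment %d owns splits %s", segment, splits)
        for split_index in splits:
            nbr_idx = np.full((nc, k), -1, dtype=np.int64)
            nbr_w = np.full((nc, k), np.inf, dtype=np.float64)
            for pos in geom.split_positions(split_index):
                tile = compute_distance_chunk(
                    work, pos, geom, eff_spec, recorder=recorder
                )
                update_topk((nbr_idx, nbr_w), tile, pos, k)
            first = split_index * nc
            n_valid = min(nc, n_points - first)
            band_idx = nbr_idx[:n_valid]
            band_w = nbr_w[:n_valid]
            if (band_idx < 0).any():
                raise AssertionError("unfilled neighbour slot after a full split")
            for r in range(n_valid):
                row = band_idx[r]
                if np.unique(row).size != k:
                    raise AssertionError(
                        f"duplicate neighbour for point {first + r}"
                    )
            lo = first * k
            targets[lo : lo + n_valid * k] = band_idx.ravel()
            weights[lo : lo + n_valid * k] = band_w.ravel()
    sources = np.repeat(np.arange(n_points, dtype=np.int64), k)
    return KnnGraph(
        sources=sources,
        targets=targets,
        weights=weights,
        k=k,
        n_points=n_points,
        metric=spec,
        row_ids=_row_ids_of(matrix),
    )


def brute_force_knn(matrix, k: int, metric="pearson") -> KnnGraph:
    """Exhaustive oracle: all pairwise distances, then a stable sort.

    Computes the full distance rows for every point, sorts ascending
    with ties broken by the smaller index (stable sort), and keeps the k
    smallest non-self entries.  Shares the tie rule of
    :func:`build_knn_graph`, so the two agree edge for edge.
    """
    values = _values_of(matrix)
    n_points = values.shape[0]
    _validate_k(k, n_points)
    spec = metric if isinstance(metric, MetricSpec) else MetricSpec(name=str(metric))
    dist = distance_block(values, values, spec)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    targets = order.ravel()
    weights = np.take_along_axis(dist, order, axis=1).ravel()
    sources = np.repeat(np.arange(n_points, dtype=np.int64), k)
    return KnnGraph(
        sources=sources,
        targets=targets,
        weights=weights,
        k=k,
        n_points=n_points,
        metric=spec,
        row_ids=_row_ids_of(matrix),
    )


def query_neighbors(graph: KnnGraph, key) -> list[tuple[object, float]]:
    """Ordered out-edges of one source: [(target, weight), ...] ascending.

    ``key`` is a row identifier (when the graph carries ids) or a
    0-based integer index.  The classic use is querying a phenotype
    "dummy probe" row for the features whose profiles track it.
    """
    if isinstance(key, str):
        if graph.row_ids is None:
            raise LookupError("graph carries no row ids; query by index")
        try:
            index = graph.row_ids.index(key)
        except ValueError:
            raise LookupError(f"unknown row id {key!r}") from None
    else:
        index = int(key)
    pairs = graph.neighbors_of(index)
    if graph.row_ids is not None:
        return [(graph.row_ids[t], w) for t, w in pairs]
    return [(t, w) for t, w in pairs]
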