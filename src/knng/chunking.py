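"""Tiling geometry of the virtual distance matrix.

The full n x n pairwise distance matrix is never materialised.  Instead
it is covered by square chunks of side ``chunk_size_nc``; the chunks
sharing a row range form a *split* (finishing a split finalises the
neighbour lists of those rows), and splits are grouped into *segments*,
each owned by one independent worker.  The point count is padded up to a
multiple of the chunk size and the dimension count up to a multiple of
the data-block size ``block_size_b`` so that all tiles align; pad
entries carry a sentinel and are skipped by the neighbour update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = ["ChunkGeometry", "ChunkPosition", "pad_dims", "plan"]


def _ceil_to_multiple(value: int, base: int) -> int:
    return -(-value // base) * base


def pad_dims(
    n_points: int, n_dims: int, chunk_size_nc: int, block_size_b: int
) -> tuple[int, int]:
    """Smallest (M, N) with M a multiple of the chunk size >= n_points and
    N a multiple of the block size >= n_dims.

    The chunk size must itself be a multiple of the block size so that a
    chunk decomposes into whole data blocks.
    """
    for name, val in (
        ("n_points", n_points),
        ("n_dims", n_dims),
        ("chunk_size_nc", chunk_size_nc),
        ("block_size_b", block_size_b),
    ):
        if val < 1:
            raise ValueError(f"{name} must be >= 1, got {val}")
    if chunk_size_nc % block_size_b != 0:
        raise ValueError(
            f"chunk size {chunk_size_nc} is not a multiple of "
            f"block size {block_size_b}"
        )
    return (
        _ceil_to_multiple(n_points, chunk_size_nc),
        _ceil_to_multiple(n_dims, block_size_b),
    )


@dataclass(frozen=True)
class ChunkPosition:
    """One chunk of the virtual distance matrix.

    ``row_offset``/``col_offset`` are the global indices of the tile's
    first row/column; ``pad_rows``/``pad_cols`` count trailing rows or
    columns lying beyond the true point count (only the last band has
    them).
    """

    split_index: int
    chunk_index: int
    row_offset: int
    col_offset: int
    is_diagonal: bool
    pad_rows: int
    pad_cols: int


@dataclass(frozen=True)
class ChunkGeometry:
    """Derived tiling plan; independent of the data values."""

    n_points: int
    n_dims: int
    chunk_size_nc: int
    block_size_b: int
    padded_points_M: int
    padded_dims_N: int
    n_chunks_per_split: int
    n_splits: int
    n_segments: int

    def position(self, split_index: int, chunk_index: int) -> ChunkPosition:
        nc = self.chunk_size_nc
        row_offset = split_index * nc
        col_offset = chunk_index * nc
        return ChunkPosition(
            split_index=split_index,
            chunk_index=chunk_index,
            row_offset=row_offset,
            col_offset=col_offset,
            is_diagonal=split_index == chunk_index,
            pad_rows=max(0, row_offset + nc - self.n_points),
            pad_cols=max(0, col_offset + nc - self.n_points),
        )

    def segment_splits(self, segment_index: int) -> list[int]:
        """Splits owned by one segment: contiguous, as even as possible."""
        if not 0 <= segment_index < self.n_segments:
            raise IndexError(f"segment {segment_index} out of range")
        parts = np.array_split(np.arange(self.n_splits), self.n_segments)
        return [int(s) for s in parts[segment_index]]

    def split_positions(self, split_index: int) -> Iterator[ChunkPosition]:
        """Chunks of one split in ascending column order."""
        for chunk_index in range(self.n_chunks_per_split):
            yield self.position(split_index, chunk_index)

    def all_positions(self) -> Iterator[ChunkPosition]:
        for segment in range(self.n_segments):
            for split_index in self.segment_splits(segment):
                yield from self.split_positions(split_index)


def plan(
    n_points: int,
    n_dims: int,
    chunk_size_nc: int = 1024,
    block_size_b: int = 16,
    n_segments: int = 1,
) -> ChunkGeometry:
    """Build the tiling plan for an n_points x n_points distance matrix.

    Segments partition whole splits; requesting more segments than there
    are splits clamps the count with a warning (tiny inputs).
    """
    if n_segments < 1:
        raise ValueError(f"n_segments must be >= 1, got {n_segments}")
    M, N = pad_dims(n_points, n_dims, chunk_size_nc, block_size_b)
    n_splits = M // chunk_size_nc
    if n_segments > n_splits:
        warnings.warn(
            f"n_segments={n_segments} exceeds the {n_splits} split(s); "
            f"clamping to {n_splits}",
            stacklevel=2,
        )
        n_segments = n_splits
    return ChunkGeometry(
        n_points=n_points,
        n_dims=n_dims,
        chunk_size_nc=chunk_size_nc,
        block_size_b=block_size_b,
        padded_points_M=M,
        padded_dims_N=N,
        n_chunks_per_split=n_splits,
        n_splits=n_splits,
        n_segments=n_segments,
    )
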