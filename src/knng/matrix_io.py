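"""Reading, writing and synthesising expression-like feature matrices.

A matrix has one row per point (a probe, gene, or metafeature) and one
column per dimension (a sample).  Rows carry unique string identifiers in
the first column of the delimited file; an optional single header line
names the sample columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MatrixFormatError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "generate_fixture",
    "fixture_block_labels",
]


class MatrixFormatError(ValueError):
    """The file cannot be parsed as a rectangular numeric matrix."""


class MatrixValidationError(ValueError):
    """The parsed matrix violates an invariant (ids, finiteness, size)."""


@dataclass
class ExpressionMatrix:
    """An n_points x n_dims numeric matrix with row and column identifiers.

    Every entry must be finite; row identifiers must be unique; at least
    two points are required (a kNN graph with k >= 1 needs a non-self
    neighbour for every point).
    """

    values: np.ndarray
    row_ids: list[str] = field(repr=False)
    col_ids: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise MatrixValidationError(
                f"values must be 2-dimensional, got ndim={self.values.ndim}"
            )
        n, d = self.values.shape
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(self.row_ids) != n:
            raise MatrixValidationError(
                f"{len(self.row_ids)} row ids for {n} rows"
            )
        if len(self.col_ids) != d:
            raise MatrixValidationError(
                f"{len(self.col_ids)} column ids for {d} columns"
            )
        if n < 2:
            raise MatrixValidationError(
                f"need at least 2 points, got {n}"
            )
        if len(set(self.row_ids)) != n:
            seen: set[str] = set()
            dup = next(r for r in self.row_ids if r in seen or seen.add(r))
            raise MatrixValidationError(f"duplicate row id {dup!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"non-finite value at row {self.row_ids[i]!r}, "
                f"column {self.col_ids[j]!r}"
            )

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        """0-based index of a row identifier; raises LookupError if absent."""
        try:
            return self.row_ids.index(row_id)
        except ValueError:
            raise LookupError(f"unknown row id {row_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def _looks_like_header(fields: list[str]) -> bool:
    """A first line is a header iff any non-id field fails to parse as float."""
    for token in fields[1:]:
        try:
            float(token)
        except ValueError:
            return True
    return False


def read_matrix(
    path, delimiter: str = "\t", has_header: bool | None = None
) -> ExpressionMatrix:
    """Read a delimited matrix: first column row id, remaining columns numeric.

    Parameters
    ----------
    path : path or file-like
    delimiter : field separator (tab by default).
    has_header : True/False to force; None auto-detects by attempting to
        parse the first line's numeric fields.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MatrixFormatError("empty matrix file")
    first = lines[0].split(delimiter)
    if len(first) < 2:
        raise MatrixFormatError(
            "each line needs an id column and at least one numeric column"
        )
    if has_header is None:
        has_header = _looks_like_header(first)

    try:
        frame = pd.read_csv(
            io.StringIO(text),
            sep=delimiter,
            header=0 if has_header else None,
            index_col=0,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"ragged or malformed rows: {exc}") from exc

    if frame.shape[1] == 0 or frame.shape[0] == 0:
        raise MatrixFormatError("matrix body is empty")
    row_ids = [str(r) for r in frame.index]
    if has_header:
        col_ids = [str(c) for c in frame.columns]
    else:
        col_ids = [f"c{j}" for j in range(frame.shape[1])]

    raw = frame.to_numpy()
    if pd.isna(raw).any():
        i, j = np.argwhere(pd.isna(raw))[0]
        raise MatrixFormatError(
            f"short/ragged row: missing value at row {row_ids[i]!r}, "
            f"column {col_ids[j]!r}"
        )
    try:
        # numpy's str->float64 conversion round-trips repr precision
        numeric = raw.astype(np.float64)
    except ValueError:
        coerced = frame.apply(pd.to_numeric, errors="coerce").to_numpy()
        i, j = np.argwhere(np.isnan(coerced) & ~pd.isna(raw))[0]
        raise MatrixFormatError(
            f"non-numeric cell {raw[i, j]!r} at row {row_ids[i]!r}, "
            f"column {col_ids[j]!r}"
        ) from None
    return ExpressionMatrix(values=numeric, row_ids=row_ids, col_ids=col_ids)


def write_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix in the same delimited layout read_matrix accepts.

    Values are written with repr precision so a read/write cycle
    reproduces the float64 content exactly.
    """
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="id")


def fixture_block_labels(n_points: int, n_blocks: int) -> np.ndarray:
    """Block membership used by generate_fixture: contiguous, near-even groups."""
    labels = np.empty(n_points, dtype=np.int64)
    for b, idx in enumerate(np.array_split(np.arange(n_points), n_blocks)):
        labels[idx] = b
    return labels


def generate_fixture(
    n_points: int,
    n_dims: int,
    n_blocks: int = 1,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Synthesise a block-structured expression matrix.

    Points are partitioned into ``n_blocks`` contiguous groups; all points
    in a group share a latent standard-normal profile, to which i.i.d.
    Gaussian noise of standard deviation ``noise_sd`` is added.  With low
    noise the nearest neighbour of a point (under any of the supported
    metrics) lies in its own block, so kNN graphs show block structure.
    Deterministic for a fixed seed.
    """
    if n_points < 2:
        raise MatrixValidationError(f"n_points must be >= 2, got {n_points}")
    if n_dims < 1:
        raise MatrixValidationError(f"n_dims must be >= 1, got {n_dims}")
    if not 1 <= n_blocks <= n_points:
        raise MatrixValidationError(
            f"n_blocks must be in [1, n_points], got {n_blocks}"
        )
    if noise_sd < 0:
        raise MatrixValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_blocks, n_dims))
    noise = rng.normal(0.0, noise_sd, (n_points, n_dims)) if noise_sd > 0 else 0.0
    labels = fixture_block_labels(n_points, n_blocks)
    values = latent[labels] + noise
    width = max(4, len(str(n_points - 1)))
    row_ids = [f"p{i:0{width}d}" for i in range(n_points)]
    col_ids = [f"s{j:03d}" for j in range(n_dims)]
    return ExpressionMatrix(values=values, row_ids=row_ids, col_ids=col_ids)
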