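"""Distance kernels: point-pair scalars and blocked (tiled) evaluation.

Four metrics are supported.  Euclidean and Manhattan are true metrics;
Pearson and Spearman are correlation similarities converted to distances
as ``d = 1 - r`` (range [0, 2]), so "nearest" means "most positively
correlated".  Rows with zero variance have no defined correlation; they
receive a large finite sentinel distance (the float32 maximum) so they
are never preferred over any real neighbour, mirroring a float_max
initialised neighbour buffer.

The blocked form accumulates partial sums over tiles of ``block_size_b``
dimensions, the access pattern of a tiled pairwise-distance kernel; the
result is independent of the tile width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "METRICS",
    "MAX_DISTANCE",
    "MetricSpec",
    "distance",
    "distance_block",
]

METRICS = ("euclidean", "manhattan", "pearson", "spearman")

#: Sentinel distance for degenerate (zero-variance) rows under
#: correlation metrics: the largest finite float32, far above the 1 - r
#: range of [0, 2] yet strictly below the +inf used for empty neighbour
#: slots.
MAX_DISTANCE = float(np.finfo(np.float32).max)

_CORRELATION = frozenset({"pearson", "spearman"})


@dataclass(frozen=True)
class MetricSpec:
    """A metric name plus the tile width used by blocked evaluation."""

    name: str = "pearson"
    block_size_b: int = 16

    def __post_init__(self) -> None:
        if self.name not in METRICS:
            raise ValueError(
                f"unknown metric {self.name!r}; choose from {METRICS}"
            )
        if self.block_size_b < 1:
            raise ValueError(
                f"block_size_b must be >= 1, got {self.block_size_b}"
            )


def _as_spec(metric) -> MetricSpec:
    if isinstance(metric, MetricSpec):
        return metric
    return MetricSpec(name=str(metric))


def _check_lengths(d: int, name: str) -> None:
    if d < 1:
        raise ValueError("vectors must have at least one dimension")
    if name in _CORRELATION and d < 2:
        raise ValueError(f"{name} distance needs at least 2 dimensions")


def distance(x, y, metric="pearson") -> float:
    """Distance between two equal-length vectors under the chosen metric."""
    spec = _as_spec(metric)
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    _check_lengths(x.size, spec.name)
    if spec.name == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if spec.name == "manhattan":
        return float(np.sum(np.abs(x - y)))
    if spec.name == "spearman":
        x, y = rankdata(x), rankdata(y)
    # Pearson on (possibly rank-transformed) vectors.
    if x.max() == x.min() or y.max() == y.min():
        return MAX_DISTANCE
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(np.dot(xc, xc))
    vy = float(np.dot(yc, yc))
    if vx <= 0.0 or vy <= 0.0:  # variance underflowed: effectively constant
        return MAX_DISTANCE
    r = float(np.dot(xc, yc) / (np.sqrt(vx) * np.sqrt(vy)))
    return 1.0 - min(1.0, max(-1.0, r))


def distance_block(X, Y, metric="pearson") -> np.ndarray:
    """All pairwise distances between rows of X (m x d) and Y (p x d).

    Entry (i, j) equals ``distance(X[i], Y[j], metric)`` up to floating
    round-off; the d axis is consumed in tiles of ``metric.block_size_b``
    columns with partial sums accumulated across tiles.
    """
    spec = _as_spec(metric)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, Y has {Y.shape[1]}"
        )
    d = X.shape[1]
    _check_lengths(d, spec.name)
    if spec.name == "spearman":
        X = rankdata(X, axis=1)
        Y = rankdata(Y, axis=1)
        return _pearson_block(X, Y, spec.block_size_b)
    if spec.name == "pearson":
        return _pearson_block(X, Y, spec.block_size_b)
    return _elementwise_block(X, Y, spec)


def _tiles(d: int, b: int):
    for lo in range(0, d, b):
        yield lo, min(lo + b, d)


def _elementwise_block(X, Y, spec: MetricSpec) -> np.ndarray:
    # Dimensions are accumulated one at a time in ascending order, so
    # every pair's distance is bit-identical however the points are
    # later tiled into chunks and whatever the tile width b.
    m, p = X.shape[0], Y.shape[0]
    acc = np.zeros((m, p))
    for lo, hi in _tiles(X.shape[1], spec.block_size_b):
        for j in range(lo, hi):
            diff = X[:, j, None] - Y[None, :, j]
            if spec.name == "euclidean":
                acc += diff * diff
            else:
                acc += np.abs(diff)
    return np.sqrt(acc) if spec.name == "euclidean" else acc


def _pearson_block(X, Y, b: int) -> np.ndarray:
    """1 - r over centred tile-accumulated sums; degenerate rows -> sentinel.

    Degeneracy (zero variance) is detected exactly from per-row extrema,
    never from a variance threshold.  Sums accumulate dimension by
    dimension in a fixed order (no shape-dependent BLAS reductions), so
    results are bit-identical across tile widths and chunk layouts.
    """
    d = X.shape[1]
    mx = X.mean(axis=1)
    my = Y.mean(axis=1)
    sxy = np.zeros((X.shape[0], Y.shape[0]))
    sxx = np.zeros(X.shape[0])
    syy = np.zeros(Y.shape[0])
    for lo, hi in _tiles(d, b):
        Xc = X[:, lo:hi] - mx[:, None]
        Yc = Y[:, lo:hi] - my[:, None]
        for j in range(hi - lo):
            sxy += Xc[:, j, None] * Yc[None, :, j]
            sxx += Xc[:, j] * Xc[:, j]
            syy += Yc[:, j] * Yc[:, j]
    # flat rows, or rows whose centred sum of squares underflowed to zero
    flat_x = (X.max(axis=1) == X.min(axis=1)) | (sxx <= 0.0)
    flat_y = (Y.max(axis=1) == Y.min(axis=1)) | (syy <= 0.0)
    denom = np.outer(
        np.sqrt(np.where(flat_x, 1.0, sxx)), np.sqrt(np.where(flat_y, 1.0, syy))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(sxy / denom, -1.0, 1.0)
    out = 1.0 - r
    out[flat_x, :] = MAX_DISTANCE
    out[:, flat_y] = MAX_DISTANCE
    return out
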