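"""scikit-learn estimator facade.

``ChunkedKNeighborsTransformer`` plays the role of
``sklearn.neighbors.KNeighborsTransformer`` but runs the chunked engine,
so the full pairwise distance matrix is never materialised.
``MetafeatureExpander`` is a feature-pair analogue of
``PolynomialFeatures``: it appends one derived column per column pair
per arithmetic operator.  Both compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .engine import build_knn_graph
from .metafeatures import OPERATORS, MetafeatureSpec, _guarded_divide
from .metrics import METRICS, MetricSpec, distance_block

__all__ = ["ChunkedKNeighborsTransformer", "MetafeatureExpander"]


class ChunkedKNeighborsTransformer(TransformerMixin, BaseEstimator):
    """Exact kNN graph of the fitted rows, computed chunk by chunk.

    Parameters
    ----------
    n_neighbors : number of neighbours per point (k).
    metric : one of {euclidean, manhattan, pearson, spearman};
        correlation metrics use the distance 1 - r.
    chunk_size : side of the square distance tiles held in memory.
    block_size : tile width over the dimension axis; the chunk size must
        be a multiple of it.
    n_segments : number of independent split groups (worker contract);
        the output never depends on it.

    Attributes
    ----------
    graph_ : KnnGraph over the fitted rows (self-edges excluded).
    n_samples_fit_, n_features_in_ : fitted data shape.
    """

    def __init__(
        self,
        n_neighbors: int = 5,
        metric: str = "pearson",
        chunk_size: int = 1024,
        block_size: int = 16,
        n_segments: int = 1,
    ) -> None:
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.chunk_size = chunk_size
        self.block_size = block_size
        self.n_segments = n_segments

    def _spec(self) -> MetricSpec:
        if self.metric not in METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; choose from {METRICS}"
            )
        return MetricSpec(name=self.metric, block_size_b=self.block_size)

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64, ensure_min_samples=2)
        self._fit_X = X
        self.n_samples_fit_ = X.shape[0]
        self.n_features_in_ = X.shape[1]
        self.graph_ = build_knn_graph(
            X,
            k=self.n_neighbors,
            metric=self._spec(),
            chunk_size_nc=self.chunk_size,
            block_size_b=self.block_size,
            n_segments=self.n_segments,
        )
        return self

    def kneighbors_graph(self) -> csr_matrix:
        """Sparse n x n distance graph of the fitted rows (no self-loops)."""
        check_is_fitted(self, "graph_")
        return self.graph_.to_sparse()

    def transform(self, X) -> csr_matrix:
        """kNN of the rows of X among the *fitted* rows.

        Follows KNeighborsTransformer semantics: no self-exclusion, so
        transforming the training data returns each point as its own
        zero-distance neighbour.  Distances are evaluated in bands of
        ``chunk_size`` query rows.
        """
        check_is_fitted(self, "graph_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        spec = self._spec()
        k = self.n_neighbors
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        for lo in range(0, X.shape[0], self.chunk_size):
            band = X[lo : lo + self.chunk_size]
            dist = distance_block(band, self._fit_X, spec)
            order = np.argsort(dist, axis=1, kind="stable")[:, :k]
            rows.append(
                np.repeat(lo + np.arange(band.shape[0], dtype=np.int64), k)
            )
            cols.append(order.ravel())
            vals.append(np.take_along_axis(dist, order, axis=1).ravel())
        return csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(X.shape[0], self.n_samples_fit_),
        )


class MetafeatureExpander(TransformerMixin, BaseEstimator):
    """Append pairwise-combined feature columns.

    For every unordered feature pair {i, j}, i < j, and every operator in
    ``operators`` (subset of difference/summation/product/division, in
    order), a new column ``op(X[:, i], X[:, j])`` is appended after the
    original columns.  Division denominators with magnitude below
    ``division_epsilon`` are clamped, sign preserved.
    """

    def __init__(
        self,
        operators: tuple[str, ...] = ("difference",),
        division_epsilon: float = 1e-12,
    ) -> None:
        self.operators = operators
        self.division_epsilon = division_epsilon

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64, ensure_min_features=2)
        # validates the operator selection
        self._metafeature_spec = MetafeatureSpec(
            operators=tuple(self.operators),
            division_epsilon=self.division_epsilon,
        )
        self.n_features_in_ = X.shape[1]
        self.pair_index_ = np.column_stack(
            np.triu_indices(self.n_features_in_, k=1)
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "pair_index_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        left = self.pair_index_[:, 0]
        right = self.pair_index_[:, 1]
        blocks = [X]
        for op in self._metafeature_spec.operators:
            a = X[:, left]
            b = X[:, right]
            if op == "difference":
                blocks.append(a - b)
            elif op == "summation":
                blocks.append(a + b)
            elif op == "product":
                blocks.append(a * b)
            else:
                blocks.append(
                    _guarded_divide(a, b, self._metafeature_spec.division_epsilon)
                )
        return np.hstack(blocks)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "pair_index_")
        if input_features is None:
            input_features = [f"x{i}" for i in range(self.n_features_in_)]
        names = list(input_features)
        for op in self._metafeature_spec.operators:
            sym = OPERATORS[op]
            names.extend(
                f"({input_features[i]}{sym}{input_features[j]})"
                for i, j in self.pair_index_
            )
        return np.asarray(names, dtype=object)
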