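"""Pairwise metafeature expansion of expression profiles.

A *metafeature* combines the profiles of two features (matrix rows)
across all samples with an arithmetic operator — difference, summation,
product or division.  Each unordered pair {i, j}, i < j, yields exactly
one metafeature per operator, so expanding n features with m operators
gives ``n + m * n*(n-1)/2`` rows: 876 features become 384,126 rows with
one operator and 1,533,876 with all four.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import ExpressionMatrix

__all__ = ["OPERATORS", "MetafeatureSpec", "count_expanded", "expand"]

logger = logging.getLogger(__name__)

#: Operator name -> infix symbol used in derived row identifiers.
OPERATORS = {
    "difference": "-",
    "summation": "+",
    "product": "*",
    "division": "/",
}


@dataclass(frozen=True)
class MetafeatureSpec:
    """Ordered operator selection plus the near-zero division guard."""

    operators: tuple[str, ...] = ("difference",)
    division_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if not self.operators:
            raise ValueError("at least one operator is required")
        unknown = [op for op in self.operators if op not in OPERATORS]
        if unknown:
            raise ValueError(
                f"unknown operator(s) {unknown}; choose from {sorted(OPERATORS)}"
            )
        if len(set(self.operators)) != len(self.operators):
            raise ValueError(f"duplicate operators in {self.operators}")
        if self.division_epsilon <= 0:
            raise ValueError("division_epsilon must be positive")


def count_expanded(n_features: int, n_operators: int) -> int:
    """Row count after expansion: n + n_ops * C(n, 2)."""
    if n_features < 2:
        raise ValueError(f"n_features must be >= 2, got {n_features}")
    if n_operators < 1:
        raise ValueError(f"n_operators must be >= 1, got {n_operators}")
    return n_features + n_operators * (n_features * (n_features - 1) // 2)


def _guarded_divide(num: np.ndarray, den: np.ndarray, eps: float) -> np.ndarray:
    """num / den with |den| < eps clamped to a signed eps denominator."""
    near_zero = np.abs(den) < eps
    n_clamped = int(near_zero.sum())
    if n_clamped:
        logger.warning(
            "division guard clamped %d near-zero denominator entries "
            "(|den| < %g)",
            n_clamped,
            eps,
        )
        den = np.where(near_zero, np.where(den < 0, -eps, eps), den)
    return num / den


def expand(matrix: ExpressionMatrix, spec: MetafeatureSpec | None = None) -> ExpressionMatrix:
    """Append one metafeature row per feature pair per operator.

    Output rows are the original n rows followed by, for each operator
    in the order given, rows ``op(row_i, row_j)`` for all i < j in
    lexicographic (i, j) order.  Asymmetric operators keep the single
    fixed orientation row_i op row_j.  New identifiers read
    ``(id_i OP id_j)``; sample columns are unchanged.
    """
    if spec is None:
        spec = MetafeatureSpec()
    n = matrix.n_points
    values = matrix.values
    left, right = np.triu_indices(n, k=1)  # lexicographic (i, j) pairs
    blocks = [values]
    ids: list[str] = list(matrix.row_ids)
    for op in spec.operators:
        a = values[left]
        b = values[right]
        if op == "difference":
            blocks.append(a - b)
        elif op == "summation":
            blocks.append(a + b)
        elif op == "product":
            blocks.append(a * b)
        else:
            blocks.append(_guarded_divide(a, b, spec.division_epsilon))
        sym = OPERATORS[op]
        rid = matrix.row_ids
        ids.extend(
            f"({rid[i]}{sym}{rid[j]})" for i, j in zip(left.tolist(), right.tolist())
        )
    return ExpressionMatrix(
        values=np.vstack(blocks), row_ids=ids, col_ids=list(matrix.col_ids)
    )
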