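"""Promoter–promoter expression correlation (Spearman and Pearson).

Spearman uses tie-averaged (fractional) ranks; Pearson p-values are the
two-sided tail of ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of
freedom.  Undefined correlations (constant vectors — common for silent
promoters in sample subsets) propagate as flagged NaN with a warning,
never as a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionTable

__all__ = [
    "CorrelationResult",
    "UndefinedCorrelationWarning",
    "spearman",
    "pearson",
    "correlation_matrix",
    "matrix_to_long",
]


class UndefinedCorrelationWarning(UserWarning):
    """A correlation was requested for a constant vector."""


@dataclass(frozen=True)
class CorrelationResult:
    row_a: str
    row_b: str
    method: str
    estimate: float
    n: int
    p_two_sided: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("spearman", "pearson"):
            raise ValueError(f"invalid method {self.method!r}")
        if np.isfinite(self.estimate) and abs(self.estimate) > 1 + 1e-12:
            raise ValueError(f"|estimate| > 1: {self.estimate}")


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired samples, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("vectors must be finite")
    return x, y


def _constant(v: np.ndarray) -> bool:
    return bool(np.all(v == v[0]))


def spearman(x, y) -> float:
    """Spearman rank correlation (tie-averaged ranks); NaN when undefined."""
    x, y = _check_pair(x, y)
    if _constant(x) or _constant(y):
        warnings.warn("constant vector: Spearman undefined", UndefinedCorrelationWarning)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided p; (NaN, NaN) when undefined."""
    x, y = _check_pair(x, y)
    if _constant(x) or _constant(y):
        warnings.warn("constant vector: Pearson undefined", UndefinedCorrelationWarning)
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(table: ExpressionTable, method: str = "spearman") -> pd.DataFrame:
    """Symmetric correlation matrix over all row pairs, in input row order.

    The diagonal is 1.0 by definition; undefined cells are NaN (flagged by
    :class:`UndefinedCorrelationWarning` at computation time).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"invalid method {method!r}")
    ids = table.row_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 rows")
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    vectors = {rid: table.row(rid) for rid in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if method == "spearman":
                est = spearman(vectors[a], vectors[b])
            else:
                est, _ = pearson(vectors[a], vectors[b])
            mat.loc[a, b] = mat.loc[b, a] = est
    return mat


def matrix_to_long(table: ExpressionTable, method: str = "spearman") -> list[CorrelationResult]:
    """All unordered row pairs as :class:`CorrelationResult` records."""
    ids = table.row_ids
    n = len(table.sample_ids)
    out: list[CorrelationResult] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if method == "spearman":
                est, p = spearman(table.row(a), table.row(b)), None
            else:
                est, p = pearson(table.row(a), table.row(b))
            out.append(CorrelationResult(a, b, method, est, n, p))
    return out
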