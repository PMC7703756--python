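"""Co-expression similarity measures.

Four related measures over a genes x samples matrix:

* Pearson correlation (PCC) between two expression vectors.
* Inner product between centered, unit-norm vectors — identical to PCC
  on scaled data.
* Weighted inner product S_w(x_i, x_j) = sum_m w_m x~_im x~_jm, where
  w is a non-negative per-sample weight vector (the learned metric).
* Mutual Rank: the geometric mean of the two reciprocal neighbor ranks
  of a gene pair in each other's similarity-sorted lists. Lower MR
  means more strongly co-expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .preprocess import ScaledExpression

__all__ = [
    "WeightVector",
    "SimilarityMatrix",
    "pcc",
    "weighted_inner",
    "pairwise_similarity",
    "cross_similarity",
    "mutual_rank",
]

#: weights below eps * max(w) count as "not selected" (optimizers rarely
#: return exact zeros)
SELECTION_EPS = 1e-8


@dataclass(frozen=True)
class WeightVector:
    """Non-negative per-sample weights defining a weighted inner product.

    ``term`` records which GO term the weights were learned for
    ("global" for the term-agnostic variant).
    """

    w: np.ndarray
    term: str = "global"

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(w < 0):
            raise ValueError("sample weights must be non-negative")

    def __len__(self) -> int:
        return self.w.shape[0]

    def selected(self, eps: float = SELECTION_EPS) -> np.ndarray:
        """Indices of samples with weight above ``eps * max(w)``."""
        if self.w.size == 0:
            return np.array([], dtype=int)
        threshold = eps * self.w.max()
        return np.flatnonzero(self.w > threshold)

    @property
    def n_selected(self) -> int:
        return int(self.selected().size)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric gene x gene similarity with its kind.

    For ``kind="mutual_rank"`` larger values mean *less* similar
    (best possible MR is 1).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.gene_ids) != values.shape[0]:
            raise ValueError("gene id count does not match matrix size")
        if self.kind not in ("pcc", "inner", "weighted_inner", "mutual_rank"):
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two expression vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("pcc requires two equal-length vectors of length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na < 1e-300 or nb < 1e-300:
        raise ValueError("pcc undefined for constant vectors")
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


def weighted_inner(a: np.ndarray, b: np.ndarray, w: WeightVector | np.ndarray) -> float:
    """S_w(a, b) = sum_m w_m a_m b_m on centered, unit-norm vectors.

    With all-ones weights this is the plain inner product and therefore
    equals the PCC of the pre-scaling vectors.
    """
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if np.any(wv < 0):
        raise ValueError("sample weights must be non-negative")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape != wv.shape:
        raise ValueError("vector/weight lengths must match")
    return float(np.sum(wv * a * b))


def pairwise_similarity(
    X: ScaledExpression,
    w: WeightVector | np.ndarray | None = None,
) -> SimilarityMatrix:
    """All-pairs (weighted) inner product over the scaled matrix.

    ``w=None`` means all-ones weights, i.e. the PCC matrix of the
    original expression vectors.
    """
    V = X.values
    if w is None:
        values = V @ V.T
        kind = "inner"
    else:
        wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
        if wv.shape != (X.n_samples,):
            raise ValueError(
                f"weight length {wv.shape} does not match sample count {X.n_samples}"
            )
        if np.any(wv < 0):
            raise ValueError("sample weights must be non-negative")
        values = (V * wv) @ V.T
        kind = "weighted_inner"
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values=values, gene_ids=X.gene_ids, kind=kind)


def cross_similarity(
    X_test: ScaledExpression | np.ndarray,
    X_train: ScaledExpression | np.ndarray,
    w: WeightVector | np.ndarray | None = None,
) -> np.ndarray:
    """(Weighted) inner products between two gene sets sharing the same samples;
    returns a test x train array."""
    A = X_test.values if isinstance(X_test, ScaledExpression) else np.asarray(X_test, float)
    B = X_train.values if isinstance(X_train, ScaledExpression) else np.asarray(X_train, float)
    if A.shape[1] != B.shape[1]:
        raise ValueError("test and train matrices must share the sample axis")
    if w is None:
        return A @ B.T
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if np.any(wv < 0):
        raise ValueError("sample weights must be non-negative")
    return (A * wv) @ B.T


def mutual_rank(
    S: SimilarityMatrix | np.ndarray,
    gene_ids: tuple[str, ...] | None = None,
    aggregation: str = "geometric",
) -> SimilarityMatrix:
    """Mutual Rank of a similarity matrix (larger input = more similar).

    rank_i(j) is the rank of gene j among all other genes sorted by
    decreasing similarity to i (best = 1, ties get average ranks; the
    diagonal is excluded). MR(i, j) aggregates rank_i(j) and rank_j(i)
    by their geometric mean (ATTED-II convention) or arithmetic mean.
    MR depends only on the similarity ranking, so any strictly monotone
    transform of the input leaves it unchanged.
    """
    if isinstance(S, SimilarityMatrix):
        values = S.values
        gene_ids = S.gene_ids
    else:
        values = np.asarray(S, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("mutual_rank requires a square matrix")
        if gene_ids is None:
            gene_ids = tuple(f"g{i}" for i in range(values.shape[0]))
    n = values.shape[0]
    if n < 3:
        raise ValueError("mutual_rank requires at least 3 genes")
    if aggregation not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    ranks = np.empty((n, n), dtype=float)
    idx = np.arange(n)
    for i in range(n):
        others = values[i, idx != i]
        # descending similarity -> rank 1 is the closest neighbor
        r = rankdata(-others, method="average")
        row = np.empty(n)
        row[idx != i] = r
        row[i] = 0.0
        ranks[i] = row
    if aggregation == "geometric":
        mr = np.sqrt(ranks * ranks.T)
    else:
        mr = (ranks + ranks.T) / 2.0
    np.fill_diagonal(mr, 0.0)
    return SimilarityMatrix(values=mr, gene_ids=tuple(gene_ids), kind="mutual_rank")
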