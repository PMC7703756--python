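"""Expression preprocessing: depth/expression filters, log transform, centering & scaling.

The pipeline mirrors the ATTED-II-style RNA-seq preparation: drop
low-coverage samples, drop lowly/rarely expressed genes, log-transform
with a small pseudocount, optionally standardize per study (batch), and
finally center every gene to mean zero and scale it to unit L2 norm.
All co-expression similarities downstream operate on the scaled matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ScaledExpression",
    "FilterReport",
    "filter_samples_by_depth",
    "filter_genes",
    "log_transform",
    "drop_singleton_batches",
    "standardize_batches",
    "center_scale",
    "preprocess_pipeline",
    "read_counts_tsv",
    "write_scaled_tsv",
]

DEFAULT_MIN_READS = 10_000_000
DEFAULT_MAX_EXPR_MIN = 100.0
DEFAULT_MEDIAN_EXPR_MIN = 1.0
DEFAULT_PSEUDOCOUNT = 0.125


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples expression matrix with identifiers and batch labels.

    ``space`` is ``"counts"`` for raw (non-negative) read counts and
    ``"log"`` after log transformation.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    batch_ids: tuple[str, ...]
    space: str = "counts"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "batch_ids", tuple(self.batch_ids))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples array")
        n_genes, n_samples = values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n_genes} rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n_samples} columns")
        if len(self.batch_ids) != n_samples:
            raise ValueError("batch_ids must have one label per sample")
        if self.space not in ("counts", "log"):
            raise ValueError(f"unknown expression space {self.space!r}")
        if self.space == "counts" and np.any(values < 0):
            raise ValueError("counts-space expression must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return replace(
            self,
            values=self.values[:, keep],
            sample_ids=tuple(np.asarray(self.sample_ids, dtype=object)[keep]),
            batch_ids=tuple(np.asarray(self.batch_ids, dtype=object)[keep]),
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return replace(
            self,
            values=self.values[keep, :],
            gene_ids=tuple(np.asarray(self.gene_ids, dtype=object)[keep]),
        )


@dataclass(frozen=True)
class ScaledExpression:
    """Per-gene zero-mean, unit-L2 expression: the substrate of all similarities."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("scaled expression must be 2-D")
        if len(self.gene_ids) != values.shape[0]:
            raise ValueError("gene id count does not match row count")
        if len(self.sample_ids) != values.shape[1]:
            raise ValueError("sample id count does not match column count")
        means = values.mean(axis=1)
        norms = np.linalg.norm(values, axis=1)
        if np.any(np.abs(means) > 1e-9):
            raise ValueError("scaled rows must have zero mean")
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("scaled rows must have unit L2 norm")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ScaledExpression":
        keep = np.asarray(keep)
        return ScaledExpression(
            values=self.values[keep, :],
            gene_ids=tuple(np.asarray(self.gene_ids, dtype=object)[keep]),
            sample_ids=self.sample_ids,
        )


@dataclass
class FilterReport:
    """Audit trail of how many samples/genes each preprocessing filter removed."""

    samples_removed_low_depth: int = 0
    genes_removed_max_expr: int = 0
    genes_removed_median_expr: int = 0
    singleton_batches_removed: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "samples_removed_low_depth": self.samples_removed_low_depth,
            "genes_removed_max_expr": self.genes_removed_max_expr,
            "genes_removed_median_expr": self.genes_removed_median_expr,
            "singleton_batches_removed": self.singleton_batches_removed,
        }


def filter_samples_by_depth(
    X: ExpressionMatrix,
    min_reads: float = DEFAULT_MIN_READS,
    mapped_reads: Sequence[float] | None = None,
) -> ExpressionMatrix:
    """Remove samples with fewer than ``min_reads`` mapped reads.

    By default the column sum of the count matrix is used as a proxy for
    mapped reads; pass ``mapped_reads`` (one value per sample, e.g. from
    sequencing metadata) to override. Samples with exactly ``min_reads``
    are retained ("fewer than" is strict).
    """
    if X.space != "counts":
        raise ValueError("depth filtering requires a counts-space matrix")
    if mapped_reads is None:
        depth = X.values.sum(axis=0)
    else:
        depth = np.asarray(mapped_reads, dtype=float)
        if depth.shape != (X.n_samples,):
            raise ValueError("mapped_reads must have one value per sample")
    keep = depth >= min_reads
    if not keep.any():
        raise ValueError(
            f"all {X.n_samples} samples have fewer than {min_reads:g} mapped reads"
        )
    return X.subset_samples(keep)


def filter_genes(
    X: ExpressionMatrix,
    max_expr_min: float = DEFAULT_MAX_EXPR_MIN,
    median_expr_min: float = DEFAULT_MEDIAN_EXPR_MIN,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove lowly expressed genes.

    A gene is dropped if its maximum expression over the (already
    depth-filtered) samples is below ``max_expr_min``, or its median
    expression is below ``median_expr_min`` (a zero-inflation guard).
    """
    if X.space != "counts":
        raise ValueError("gene filtering operates on counts")
    row_max = X.values.max(axis=1)
    row_median = np.median(X.values, axis=1)
    fail_max = row_max < max_expr_min
    fail_median = row_median < median_expr_min
    keep = ~(fail_max | fail_median)
    if not keep.any():
        raise ValueError("all genes removed by expression filters")
    report = FilterReport(
        genes_removed_max_expr=int(fail_max.sum()),
        genes_removed_median_expr=int((fail_median & ~fail_max).sum()),
    )
    return X.subset_genes(keep), report


def log_transform(
    X: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    base: float = 2.0,
) -> ExpressionMatrix:
    """log(count + pseudocount); base 2 by default (the log base only rescales
    rows uniformly and cancels in PCC and in the centered/scaled matrix)."""
    if X.space != "counts":
        raise ValueError("log_transform expects counts")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = np.log(X.values + pseudocount) / np.log(base)
    return replace(X, values=values, space="log")


def drop_singleton_batches(X: ExpressionMatrix) -> ExpressionMatrix:
    """Remove samples from studies (batches) represented by a single sample,
    so that per-batch variances are estimable."""
    labels = np.asarray(X.batch_ids, dtype=object)
    uniq, counts = np.unique(labels, return_counts=True)
    multi = set(uniq[counts >= 2])
    keep = np.array([b in multi for b in labels])
    if keep.all():
        return X
    if not keep.any():
        raise ValueError("every study has a single sample; nothing left after filtering")
    return X.subset_samples(keep)


def standardize_batches(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-batch gene-wise mean/variance standardization.

    A lightweight batch-effect adjustment: within every study each gene
    is centered and scaled to unit variance, then the gene's global
    log-space mean and pooled SD are restored. An externally corrected
    (e.g. empirical-Bayes) matrix can be supplied instead; this function
    is optional in the pipeline.
    """
    if X.space != "log":
        raise ValueError("batch standardization operates in log space")
    values = X.values.copy()
    labels = np.asarray(X.batch_ids, dtype=object)
    grand_mean = values.mean(axis=1, keepdims=True)
    grand_sd = values.std(axis=1, keepdims=True)
    for batch in np.unique(labels):
        cols = labels == batch
        if cols.sum() < 2:
            raise ValueError(f"batch {batch!r} has a single sample; drop it first")
        block = values[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values[:, cols] = (block - mu) / sd * np.where(grand_sd > 0, grand_sd, 1.0) + grand_mean
    return replace(X, values=values)


def center_scale(X: ExpressionMatrix | np.ndarray, gene_ids=None, sample_ids=None) -> ScaledExpression:
    """Center each gene to mean zero and scale to unit L2 norm.

    On the resulting rows the plain inner product of two genes equals
    their Pearson correlation. Constant rows have no direction after
    centering and are rejected.
    """
    if isinstance(X, ExpressionMatrix):
        values = X.values
        gene_ids = X.gene_ids
        sample_ids = X.sample_ids
    else:
        values = np.asarray(X, dtype=float)
        if gene_ids is None:
            gene_ids = tuple(f"g{i}" for i in range(values.shape[0]))
        if sample_ids is None:
            sample_ids = tuple(f"s{j}" for j in range(values.shape[1]))
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = norms < 1e-12
    if bad.any():
        offenders = [gene_ids[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"constant expression rows cannot be scaled: {offenders}")
    scaled = centered / norms[:, None]
    # renormalize once more to push rounding error below the type invariant
    scaled = scaled - scaled.mean(axis=1, keepdims=True)
    scaled = scaled / np.linalg.norm(scaled, axis=1, keepdims=True)
    return ScaledExpression(values=scaled, gene_ids=tuple(gene_ids), sample_ids=tuple(sample_ids))


def preprocess_pipeline(
    X: ExpressionMatrix,
    min_reads: float = DEFAULT_MIN_READS,
    max_expr_min: float = DEFAULT_MAX_EXPR_MIN,
    median_expr_min: float = DEFAULT_MEDIAN_EXPR_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    mapped_reads: Sequence[float] | None = None,
    batch_standardize: bool = False,
) -> tuple[ScaledExpression, FilterReport]:
    """Full preprocessing in the canonical order:

    sample depth filter -> gene expression filters -> log transform ->
    singleton-batch removal (-> optional per-batch standardization) ->
    center & scale. The order matters: gene filters look only at samples
    that survived the depth filter.
    """
    n0 = X.n_samples
    X = filter_samples_by_depth(X, min_reads=min_reads, mapped_reads=mapped_reads)
    n_after_depth = X.n_samples
    X, report = filter_genes(X, max_expr_min=max_expr_min, median_expr_min=median_expr_min)
    report.samples_removed_low_depth = n0 - n_after_depth
    X = log_transform(X, pseudocount=pseudocount)
    n_before_batch = X.n_samples
    X = drop_singleton_batches(X)
    report.singleton_batches_removed = n_before_batch - X.n_samples
    if batch_standardize:
        X = standardize_batches(X)
    return center_scale(X), report


def read_counts_tsv(
    counts_path: str,
    metadata_path: str | None = None,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a genes x samples count table (first column = gene ids, header =
    sample ids) and optional sample metadata with ``sample_id``/``batch_id``
    (and optionally ``mapped_reads``) columns."""
    df = pd.read_csv(counts_path, sep=sep, index_col=0)
    sample_ids = tuple(str(c) for c in df.columns)
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=sep, dtype={"sample_id": str, "batch_id": str})
        meta = meta.set_index("sample_id")
        missing = [s for s in sample_ids if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        batch_ids = tuple(str(meta.loc[s, "batch_id"]) for s in sample_ids)
    else:
        batch_ids = tuple("batch0" for _ in sample_ids)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=sample_ids,
        batch_ids=batch_ids,
    )


def write_scaled_tsv(X: ScaledExpression, path: str) -> None:
    df = pd.DataFrame(X.values, index=list(X.gene_ids), columns=list(X.sample_ids))
    df.to_csv(path, sep="\t", index_label="gene_id")
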