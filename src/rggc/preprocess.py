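"""Fixed preprocessing chain: log2(x+1) -> quantile normalization -> z-score.

The chain turns a raw genes x cells count matrix into the column-normalized
expression matrix X consumed by the graph model: every cell (column) ends up
with zero mean and unit variance, so inner products between cells are
correlations up to a constant.  Order is fixed — log transform to tame the
count skew, quantile normalization across cells to equalize sequencing
depth, then a per-cell z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "log_transform",
    "quantile_normalize",
    "zscore_cells",
    "preprocess",
    "filter_genes",
]


@dataclass
class ExpressionMatrix:
    """Real-valued genes x cells matrix with a record of applied transforms."""

    X: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (genes x cells)")
        p, n = self.X.shape
        if not self.gene_ids:
            self.gene_ids = [f"g{i + 1}" for i in range(p)]
        if not self.cell_ids:
            self.cell_ids = [f"c{j + 1}" for j in range(n)]

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def _derive(self, X: np.ndarray, step: str) -> "ExpressionMatrix":
        return ExpressionMatrix(X, self.gene_ids, self.cell_ids, self.provenance + [step])


def log_transform(counts: CountMatrix | ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise ``log2(x + 1)``; zeros stay zero."""
    if isinstance(counts, CountMatrix):
        em = ExpressionMatrix(counts.counts.astype(np.float64), counts.gene_ids, counts.cell_ids)
    else:
        em = counts
    return em._derive(np.log2(em.X + 1.0), "log2(x+1)")


def quantile_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Force every cell (column) onto the common reference distribution.

    The reference is the mean across cells of the sorted columns.  Tied
    values within a column all receive the mean of the reference values
    over their rank span, so the result does not depend on the input
    ordering of tied entries — essential for log counts, where zeros tie
    massively.
    """
    A = X.X
    p, n = A.shape
    if p < 2:
        raise ValueError("quantile normalization needs at least 2 genes")
    order = np.argsort(A, axis=0, kind="stable")
    srt = np.take_along_axis(A, order, axis=0)
    ref = srt.mean(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(ref)])

    out = np.empty_like(A)
    for j in range(n):
        sv = srt[:, j]
        # boundaries of runs of equal values in the sorted column
        starts = np.flatnonzero(np.concatenate([[True], sv[1:] != sv[:-1]]))
        ends = np.concatenate([starts[1:], [p]])
        run_means = (cum[ends] - cum[starts]) / (ends - starts)
        if len(starts) == 1:
            logger.warning("constant column %d mapped to the grand reference mean", j)
        vals = np.repeat(run_means, ends - starts)
        out[order[:, j], j] = vals
    return X._derive(out, "quantile_normalize")


def zscore_cells(X: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each cell to zero mean, unit population variance.

    A zero-variance cell carries no signal; its column is set to all zeros
    and a warning is logged rather than dividing by zero.
    """
    A = X.X
    if A.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 genes")
    mu = A.mean(axis=0, keepdims=True)
    sd = A.std(axis=0, keepdims=True)  # population sd (ddof=0)
    degenerate = sd[0] == 0.0
    if degenerate.any():
        logger.warning("%d zero-variance cell(s) set to all zeros", int(degenerate.sum()))
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    out = (A - mu) / sd_safe
    out[:, degenerate] = 0.0
    return X._derive(out, "zscore_cells")


def filter_genes(counts: CountMatrix, min_cells: int) -> CountMatrix:
    """Keep genes expressed (count > 0) in at least ``min_cells`` cells.

    Off by default in the pipeline: the method is designed to run on the
    raw expression matrix with no feature selection.
    """
    keep = (counts.counts > 0).sum(axis=1) >= min_cells
    return CountMatrix(
        counts.counts[keep],
        [g for g, k in zip(counts.gene_ids, keep) if k],
        counts.cell_ids,
    )


def preprocess(counts: CountMatrix) -> ExpressionMatrix:
    """Full chain: log2(x+1), quantile normalization, per-cell z-score."""
    return zscore_cells(quantile_normalize(log_transform(counts)))
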