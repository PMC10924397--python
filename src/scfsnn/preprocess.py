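"""Count-matrix containers, gene filtering and normalization.

Raw UMI/read counts are library-size normalized to the median total count,
log1p-transformed and gene-standardized:

    x_ij = (log(x'_ij * d0 / d_i + 1) - m_j) / s_j

where d_i is the total count of cell i, d0 the median of the d_i over the
fitting cells, and m_j, s_j the mean and standard deviation of the
log-normalized values of gene j.  The fitted statistics (d0, m_j, s_j) are
retained so held-out cells can be transformed without touching them during
model fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "Labels",
    "ProcessedMatrix",
    "filter_genes",
    "fit_normalize",
    "apply_normalize",
]


@dataclass
class CountMatrix:
    """Raw counts, cells as rows and genes as columns."""

    values: np.ndarray  # (n_cells, n_genes) non-negative integers
    gene_ids: np.ndarray  # (n_genes,) str
    cell_ids: np.ndarray  # (n_cells,) str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise ValueError(f"need at least 2 cells and 1 gene, got {n} x {p}")
        if self.gene_ids.shape[0] != p:
            raise ValueError("gene_ids length does not match number of columns")
        if self.cell_ids.shape[0] != n:
            raise ValueError("cell_ids length does not match number of rows")
        if len(set(self.gene_ids.tolist())) != p:
            raise ValueError("duplicate gene_ids")
        if np.any(self.values < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                bad = np.argwhere(self.values != np.round(self.values))[0]
                raise ValueError(
                    f"non-integer count at cell {bad[0]}, gene {bad[1]}: "
                    f"{self.values[bad[0], bad[1]]!r}"
                )
            self.values = self.values.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[idx], self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[:, idx], self.gene_ids[idx], self.cell_ids)


@dataclass
class Labels:
    """Integer class labels 0..K-1 for each cell."""

    y: np.ndarray
    n_classes: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.n_classes == 0:
            self.n_classes = int(self.y.max()) + 1 if self.y.size else 0
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        present = np.unique(self.y)
        if present.min() < 0 or present.max() >= self.n_classes:
            raise ValueError("labels outside 0..K-1")
        if present.size != self.n_classes:
            missing = sorted(set(range(self.n_classes)) - set(present.tolist()))
            raise ValueError(f"classes with no members: {missing}")

    def subset(self, idx: np.ndarray) -> "Labels":
        return Labels(self.y[idx], self.n_classes)


@dataclass
class ProcessedMatrix:
    """Normalized/log/standardized expression plus the fitted statistics."""

    values: np.ndarray  # (n, p) float
    d0: float  # median total count of the fitting cells
    cell_totals: np.ndarray  # (n,) totals of the fitting cells
    gene_means: np.ndarray  # (p,) m_j on log-normalized scale
    gene_sds: np.ndarray  # (p,) s_j on log-normalized scale
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]


def filter_genes(counts: CountMatrix, max_zero_fraction: float = 0.8) -> CountMatrix:
    """Drop genes whose fraction of zero counts exceeds ``max_zero_fraction``.

    A gene observed as zero in more than the given fraction of cells carries
    too little information to survive; order of the remaining genes is
    preserved.  ``max_zero_fraction = 1.0`` keeps everything.
    """
    if not 0.0 < max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in (0, 1]")
    zero_frac = np.mean(counts.values == 0, axis=0)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValueError(
            "empty-after-filter: every gene has zero counts in more than "
            f"{max_zero_fraction:.0%} of cells"
        )
    if keep.all():
        return counts
    return counts.subset_genes(np.flatnonzero(keep))


def _log_normalize(values: np.ndarray, d0: float, totals: np.ndarray) -> np.ndarray:
    return np.log1p(values * (d0 / totals[:, None]))


def fit_normalize(counts: CountMatrix, ddof: int = 1) -> ProcessedMatrix:
    """Fit and apply total-count normalization, log1p and gene standardization.

    Parameters
    ----------
    counts
        Raw counts of the fitting (training) cells.
    ddof
        Delta degrees of freedom for the gene standard deviation; 1 (sample
        convention) by default.

    Zero-variance genes on the log-normalized scale are dropped with a
    warning: they cannot be standardized and carry no class signal.
    """
    totals = counts.values.sum(axis=1).astype(np.float64)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0)
        names = counts.cell_ids[bad[:5]].tolist()
        raise ValueError(f"cells with zero total counts: {names}")
    d0 = float(np.median(totals))
    logn = _log_normalize(counts.values.astype(np.float64), d0, totals)
    m = logn.mean(axis=0)
    s = logn.std(axis=0, ddof=ddof)
    keep = s > 0
    if not keep.all():
        dropped = counts.gene_ids[~keep].tolist()
        msg = f"dropping {len(dropped)} zero-variance gene(s) after log-normalization"
        logger.warning("%s: %s", msg, dropped[:10])
        warnings.warn(msg, stacklevel=2)
        logn, m, s = logn[:, keep], m[keep], s[keep]
        gene_ids = counts.gene_ids[keep]
    else:
        gene_ids = counts.gene_ids
    return ProcessedMatrix(
        values=(logn - m) / s,
        d0=d0,
        cell_totals=totals,
        gene_means=m,
        gene_sds=s,
        gene_ids=gene_ids,
    )


def apply_normalize(counts: CountMatrix, fitted: ProcessedMatrix) -> np.ndarray:
    """Transform new cells with statistics fitted elsewhere.

    Only the per-cell totals d_i come from the new data; d0, m_j and s_j are
    the fitted ones, so held-out cells never influence the transform.
    """
    if fitted.gene_ids is not None and (
        counts.n_genes != len(fitted.gene_ids)
        or not np.array_equal(counts.gene_ids, fitted.gene_ids)
    ):
        raise ValueError("gene_ids of counts do not match the fitted matrix")
    totals = counts.values.sum(axis=1).astype(np.float64)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0)
        raise ValueError(f"cells with zero total counts: {counts.cell_ids[bad[:5]].tolist()}")
    logn = _log_normalize(counts.values.astype(np.float64), fitted.d0, totals)
    return (logn - fitted.gene_means) / fitted.gene_sds
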