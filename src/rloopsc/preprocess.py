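"""QC filtering, normalization, variable-gene selection and scaling.

Thresholds mirror standard droplet scRNA-seq practice: cells expressing
fewer than 300 genes or with more than 8% mitochondrial counts are dropped
first, then genes detected in fewer than 3 remaining cells. Normalization is
the log1p of counts rescaled to a fixed total per cell ("LogNormalize");
variable genes come from a standardized-variance ("vst") scheme.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """All observations were removed by a filter."""


def qc_filter(
    m: CountMatrix,
    min_genes_per_cell: int = 300,
    min_cells_per_gene: int = 3,
    max_mito_fraction: float = 0.08,
    mito_pattern: str = "^MT-",
) -> CountMatrix:
    """Remove low-quality cells, then genes detected in too few cells.

    Cells are removed when they express strictly fewer than
    ``min_genes_per_cell`` genes OR their mitochondrial fraction strictly
    exceeds ``max_mito_fraction``; genes detected in strictly fewer than
    ``min_cells_per_gene`` retained cells are then removed. Order is fixed
    (cells first) so gene detection counts refer to the retained cells.
    """
    counts = sp.csr_matrix(m.counts)
    genes_per_cell = counts.getnnz(axis=1)
    mito_mask = np.array([bool(re.search(mito_pattern, g)) for g in m.gene_names])
    totals = np.asarray(counts.sum(axis=1)).ravel()
    mito_counts = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    keep_cells = (genes_per_cell >= min_genes_per_cell) & (mito_frac <= max_mito_fraction)
    logger.info(
        "qc_filter: removed %d/%d cells (<%d genes: %d; mito >%g: %d)",
        (~keep_cells).sum(), m.n_cells, min_genes_per_cell,
        (genes_per_cell < min_genes_per_cell).sum(),
        max_mito_fraction, (mito_frac > max_mito_fraction).sum(),
    )
    if not keep_cells.any():
        raise EmptyResultError("qc_filter removed every cell")

    sub = counts[keep_cells]
    cells_per_gene = sub.getnnz(axis=0)
    keep_genes = cells_per_gene >= min_cells_per_gene
    logger.info(
        "qc_filter: removed %d/%d genes detected in <%d cells",
        (~keep_genes).sum(), m.n_genes, min_cells_per_gene,
    )
    return m.subset(cells=np.flatnonzero(keep_cells), genes=np.flatnonzero(keep_genes))


def lognormalize(m: CountMatrix, scale_factor: float = 10_000) -> CountMatrix:
    """Add a ``normalized`` layer: ln(1 + scale_factor * count / cell_total)."""
    counts = m.dense_counts()
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; run qc_filter first")
    out = m.copy()
    out.layers["normalized"] = np.log1p(scale_factor * counts / totals[:, None])
    return out


def select_hvg(m: CountMatrix, n: int = 2000, loess_span: float = 0.3) -> list:
    """Top-``n`` highly variable genes by the standardized-variance scheme.

    Fits a loess of log10(variance) on log10(mean) of the raw counts, then
    ranks genes by the variance of their standardized (clipped at
    sqrt(n_cells)) counts. Deterministic given the matrix.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > m.n_genes:
        raise ValueError(f"n={n} exceeds gene count {m.n_genes}")
    counts = m.dense_counts()
    n_cells = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    score = np.zeros(m.n_genes)
    usable = (mean > 0) & (var > 0)
    if usable.sum() >= 3:
        lm, lv = np.log10(mean[usable]), np.log10(var[usable])
        fit = lowess(lv, lm, frac=loess_span, return_sorted=False)
        expected_sd = np.sqrt(10**fit)
        clip = np.sqrt(n_cells)
        z = (counts[:, usable] - mean[usable]) / expected_sd
        np.clip(z, -clip, clip, out=z)
        score[usable] = z.var(axis=0, ddof=1)
    order = np.lexsort((np.arange(m.n_genes), -score))
    return list(m.gene_names[order[:n]])


def scale_genes(m: CountMatrix, clip: float = 10.0) -> CountMatrix:
    """Add ``centered`` and ``scaled`` layers (per-gene z-score, clipped).

    Zero-variance genes scale to 0.
    """
    if "normalized" not in m.layers:
        raise ValueError("normalized layer required; run lognormalize first")
    X = m.layers["normalized"]
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    centered = X - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    np.clip(scaled, -clip, clip, out=scaled)
    out = m.copy()
    out.layers["centered"] = centered
    out.layers["scaled"] = scaled
    return out
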