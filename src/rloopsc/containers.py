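"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse cell x gene count matrix with per-cell metadata and derived layers.

    Attributes
    ----------
    counts
        Non-negative integer matrix, cells as rows, genes as columns (CSR).
    gene_names, cell_names
        Unique identifiers for columns / rows.
    cell_meta
        Per-cell table indexed by cell name (sample, condition, cell_type,
        optional survival fields).
    layers
        Derived dense real matrices with the same shape as ``counts``
        (``"normalized"``, ``"centered"``, ``"scaled"``).
    """

    counts: sp.csr_matrix
    gene_names: pd.Index
    cell_names: pd.Index
    cell_meta: pd.DataFrame
    layers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = pd.Index(self.gene_names)
        self.cell_names = pd.Index(self.cell_names)
        if self.counts.shape != (len(self.cell_names), len(self.gene_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_names)} cells x {len(self.gene_names)} genes"
            )
        if self.gene_names.has_duplicates:
            raise ValueError("duplicate gene names")
        if self.cell_names.has_duplicates:
            raise ValueError("duplicate cell names")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_names)
        else:
            self.cell_meta = self.cell_meta.reindex(self.cell_names)
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """Positions of ``genes`` in the column order; missing genes error."""
        idx = self.gene_names.get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return idx

    def subset(self, cells=None, genes=None) -> "CountMatrix":
        """Positional subset along either axis, propagating layers and metadata."""
        ci = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        gi = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        return CountMatrix(
            counts=self.counts[ci][:, gi],
            gene_names=self.gene_names[gi],
            cell_names=self.cell_names[ci],
            cell_meta=self.cell_meta.iloc[ci],
            layers={k: v[np.ix_(ci, gi)] for k, v in self.layers.items()},
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.copy(),
            gene_names=self.gene_names.copy(),
            cell_names=self.cell_names.copy(),
            cell_meta=self.cell_meta.copy(),
            layers={k: v.copy() for k, v in self.layers.items()},
        )

    def dense_counts(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)
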