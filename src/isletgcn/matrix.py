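"""In-memory containers for gene-by-cell expression data.

Both containers store a dense gene-major matrix together with string
identifiers.  Gene-major orientation mirrors the on-disk triplet layout
(genes as rows of ``matrix.mtx``); helpers exist to subset by id without
losing the id <-> row/column correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def _as_index(ids: Iterable[str], what: str) -> pd.Index:
    idx = pd.Index([str(i) for i in ids], dtype=object)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} ids, e.g. {dup}")
    return idx


@dataclass
class CountMatrix:
    """Raw gene x cell non-negative integer counts."""

    gene_ids: pd.Index
    cell_ids: pd.Index
    values: np.ndarray  # shape (n_genes, n_cells), integer

    def __post_init__(self) -> None:
        self.gene_ids = _as_index(self.gene_ids, "gene")
        self.cell_ids = _as_index(self.cell_ids, "cell")
        values = np.asarray(self.values)
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("count matrix contains non-integer values")
            values = np.round(values).astype(np.int64)
        if values.size and values.min() < 0:
            raise ValueError("count matrix contains negative values")
        self.values = values

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        idx = self.gene_ids.get_indexer(genes)
        missing = [g for g, i in zip(genes, idx) if i < 0]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return idx

    def cell_index(self, cells: Sequence[str]) -> np.ndarray:
        idx = self.cell_ids.get_indexer(cells)
        missing = [c for c, i in zip(cells, idx) if i < 0]
        if missing:
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return idx

    def subset_cells(self, cells: Sequence[str]) -> "CountMatrix":
        idx = self.cell_index(cells)
        return CountMatrix(self.gene_ids, pd.Index(cells), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class NormalizedMatrix:
    """log2(scaled + 1) expression with the scale factor and exclusion list used.

    ``excluded_genes`` are the genes omitted from each cell's library-size
    denominator (they are still present as rows, scaled by the same
    denominator).
    """

    gene_ids: pd.Index
    cell_ids: pd.Index
    values: np.ndarray  # shape (n_genes, n_cells), float
    scale_factor: float = 1e5
    excluded_genes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.gene_ids = _as_index(self.gene_ids, "gene")
        self.cell_ids = _as_index(self.cell_ids, "cell")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match ids")
        if self.values.size and self.values.min() < -1e-12:
            raise ValueError("normalized values must be >= 0")
        self.excluded_genes = tuple(self.excluded_genes)

    n_genes = CountMatrix.n_genes
    n_cells = CountMatrix.n_cells
    gene_index = CountMatrix.gene_index
    cell_index = CountMatrix.cell_index

    def subset_cells(self, cells: Sequence[str]) -> "NormalizedMatrix":
        idx = self.cell_index(cells)
        return NormalizedMatrix(
            self.gene_ids,
            pd.Index(cells),
            self.values[:, idx],
            scale_factor=self.scale_factor,
            excluded_genes=self.excluded_genes,
        )

    def subset_genes(self, genes: Sequence[str]) -> "NormalizedMatrix":
        idx = self.gene_index(genes)
        return NormalizedMatrix(
            pd.Index(genes),
            self.cell_ids,
            self.values[idx, :],
            scale_factor=self.scale_factor,
            excluded_genes=self.excluded_genes,
        )

    def linear(self) -> np.ndarray:
        """Back-transform to the linear (TPM/TP0.1M) scale: 2**value - 1."""
        return np.exp2(self.values) - 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)
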