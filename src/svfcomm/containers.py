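"""Core in-memory containers for droplet scRNA-seq data.

The pipeline works on three lightweight containers: :class:`CountMatrix`
(raw UMI counts, cells x genes, sparse), :class:`NormalizedMatrix`
(log-CPM values derived from a count matrix) and
:class:`ClusterAssignment` (cell barcode -> cell-type label). They are
deliberately thinner than an ``AnnData``: each carries exactly the state
the downstream stages are specified against, and validates it on
construction.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "MITO_PREFIXES",
    "CountMatrix",
    "NormalizedMatrix",
    "ClusterAssignment",
    "mito_flags_from_names",
]

#: Gene-name prefixes treated as mitochondrial by default (mouse ``mt-``,
#: human ``MT-``). Overridable by an explicit gene list where used.
MITO_PREFIXES = ("mt-", "MT-", "Mt-")


def mito_flags_from_names(
    gene_names: Sequence[str],
    mito_genes: Sequence[str] | None = None,
) -> np.ndarray:
    """Boolean mitochondrial flag per gene.

    By default a gene is mitochondrial iff its name starts with one of
    :data:`MITO_PREFIXES`; passing ``mito_genes`` replaces the prefix rule
    with an explicit membership test.
    """
    if mito_genes is not None:
        mito_set = set(mito_genes)
        return np.array([g in mito_set for g in gene_names], dtype=bool)
    return np.array([g.startswith(MITO_PREFIXES) for g in gene_names], dtype=bool)


def _as_unique_index(values, what: str) -> pd.Index:
    idx = pd.Index(np.asarray(values, dtype=object), dtype=object)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dup}")
    return idx


@dataclasses.dataclass
class CountMatrix:
    """Raw cells x genes non-negative integer counts.

    Parameters
    ----------
    counts
        Cells x genes matrix; coerced to CSR. Negative entries are rejected.
    barcodes, gene_names
        Unique identifiers for rows and columns.
    is_mito
        Boolean flag per gene; computed from the gene names by the prefix
        rule when omitted.
    """

    counts: sp.csr_matrix
    barcodes: pd.Index
    gene_names: pd.Index
    is_mito: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.barcodes = _as_unique_index(self.barcodes, "barcodes")
        self.gene_names = _as_unique_index(self.gene_names, "gene names")
        if self.counts.shape != (len(self.barcodes), len(self.gene_names)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.gene_names)} genes"
            )
        if self.is_mito is None:
            self.is_mito = mito_flags_from_names(self.gene_names)
        self.is_mito = np.asarray(self.is_mito, dtype=bool)
        if self.is_mito.shape != (len(self.gene_names),):
            raise ValueError("is_mito length must equal the number of genes")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    # -- per-cell QC covariates -----------------------------------------
    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with count > 0, per cell."""
        return np.diff(self.counts.indptr)

    def mito_fraction(self) -> np.ndarray:
        """Mitochondrial fraction of each cell's counts (0 for empty cells)."""
        total = self.total_counts().astype(float)
        mito = np.asarray(self.counts[:, self.is_mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
        return frac

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            counts=self.counts[index],
            barcodes=self.barcodes[index],
            gene_names=self.gene_names,
            is_mito=self.is_mito,
        )

    def subset_genes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            counts=self.counts[:, index],
            barcodes=self.barcodes,
            gene_names=self.gene_names[index],
            is_mito=self.is_mito[index],
        )


@dataclasses.dataclass
class NormalizedMatrix:
    """Log-CPM expression values, ``ln(count / total * scale_factor + 1)``.

    For every cell with a positive total count,
    ``sum(expm1(row)) == scale_factor`` by construction; all-zero cells
    stay all-zero.
    """

    values: sp.csr_matrix
    barcodes: pd.Index
    gene_names: pd.Index
    scale_factor: float = 1e6
    is_mito: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.barcodes = _as_unique_index(self.barcodes, "barcodes")
        self.gene_names = _as_unique_index(self.gene_names, "gene names")
        if self.values.shape != (len(self.barcodes), len(self.gene_names)):
            raise ValueError("values shape does not match barcodes x genes")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.is_mito is not None:
            self.is_mito = np.asarray(self.is_mito, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def linear(self) -> sp.csr_matrix:
        """Linear-scale (CPM) values, ``expm1`` of the stored log values."""
        out = self.values.copy()
        out.data = np.expm1(out.data)
        return out

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_genes(self, index) -> "NormalizedMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return NormalizedMatrix(
            values=self.values[:, index],
            barcodes=self.barcodes,
            gene_names=self.gene_names[index],
            scale_factor=self.scale_factor,
            is_mito=None if self.is_mito is None else self.is_mito[index],
        )


@dataclasses.dataclass
class ClusterAssignment:
    """Cell barcode -> cell-type label, plus the parameters that produced it."""

    labels: pd.Series
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = pd.Series(self.labels)
        labels = labels.astype(object).map(str)
        if labels.index.has_duplicates:
            raise ValueError("duplicate barcodes in cluster assignment")
        if (labels.map(len) == 0).any():
            raise ValueError("empty cluster labels are not allowed")
        self.labels = labels

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def barcodes(self) -> pd.Index:
        return self.labels.index

    def types(self) -> list[str]:
        """Cell-type labels in deterministic (sorted) order."""
        return sorted(set(self.labels))

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(self.types())

    def codes(self) -> tuple[np.ndarray, list[str]]:
        """Integer codes (per cell) plus the label order they index into."""
        types = self.types()
        lookup = {t: i for i, t in enumerate(types)}
        codes = np.fromiter(
            (lookup[v] for v in self.labels), dtype=np.int64, count=len(self.labels)
        )
        return codes, types

    def subset(self, barcodes) -> "ClusterAssignment":
        return ClusterAssignment(self.labels.loc[barcodes], dict(self.params))
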