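"""Core in-memory containers for the QC pipeline.

A :class:`CountMatrix` is a genes x droplets integer count matrix (the raw
digital gene expression, DGE, of a droplet run) backed by a scipy sparse
matrix.  A :class:`GeneSet` is a named collection of gene symbols
(mitochondrial, ribosomal, housekeeping, ssHEG, signature or marker lists).
Per-droplet QC metrics live in a plain :class:`pandas.DataFrame` with the
fixed column set :data:`QC_COLUMNS` ("QC table").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneSet",
    "QC_COLUMNS",
    "QC_METRIC_COLUMNS",
    "validate_qc_table",
]

#: Fixed column order of a QC table as written to disk.
QC_COLUMNS = (
    "barcode",
    "nUMI",
    "nGene",
    "percent_mito",
    "percent_ribo",
    "mito_ribo_ratio",
    "percent_hk",
    "ssheg_gene_pct",
    "ssheg_count_pct",
    "no_counts",
    "label",
    "predicted_class",
)

#: The numeric metric columns (everything except identity/flag/class columns).
QC_METRIC_COLUMNS = (
    "nUMI",
    "nGene",
    "percent_mito",
    "percent_ribo",
    "mito_ribo_ratio",
    "percent_hk",
    "ssheg_gene_pct",
    "ssheg_count_pct",
)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (bare symbols, no alias resolution)."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes: Iterable[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "genes", frozenset(str(g) for g in genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))

    def intersection(self, other: Iterable[str]) -> "GeneSet":
        return GeneSet(self.name, self.genes & frozenset(other))


@dataclass
class CountMatrix:
    """Raw genes x droplets integer count matrix.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_genes, n_droplets)``.  Any
        scipy sparse matrix or dense array is accepted and stored as CSR.
    gene_ids
        Unique gene symbols, one per row.
    barcodes
        Unique droplet barcodes, one per column.
    sample_id
        Free-text label for the sequenced sample.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        counts = sp.csr_matrix(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if counts.nnz:
            data = counts.data
            if np.any(data < 0):
                raise ValueError("count matrix contains negative entries")
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise ValueError("count matrix contains non-integer entries")
                counts = counts.astype(np.int64)
        counts = counts.astype(np.int64)
        counts.sum_duplicates()
        counts.eliminate_zeros()
        self.counts = counts
        for what, labels in (("gene IDs", self.gene_ids), ("barcodes", self.barcodes)):
            if len(set(labels)) != len(labels):
                dupes = pd.Index(labels)
                dupes = sorted(set(dupes[dupes.duplicated()]))
                raise ValueError(f"duplicate {what}: {dupes[:5]}")

    # -- shape ---------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_droplets(self) -> int:
        return self.counts.shape[1]

    # -- per-droplet / per-gene summaries ------------------------------------
    def umi_per_droplet(self) -> np.ndarray:
        """Total counts (nUMI) per droplet."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_droplet(self) -> np.ndarray:
        """Number of genes with count > 0 (nGene) per droplet."""
        return np.asarray(self.counts.getnnz(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        """Total counts per gene across all droplets."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def total_counts(self) -> int:
        return int(self.counts.sum())

    # -- indexing ------------------------------------------------------------
    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given gene symbols (absent symbols ignored)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array(sorted(lookup[g] for g in genes if g in lookup), dtype=int)

    def subset_droplets(self, barcodes: Sequence[str]) -> "CountMatrix":
        """Column subset, preserving the order given in ``barcodes``."""
        lookup = {b: i for i, b in enumerate(self.barcodes)}
        missing = [b for b in barcodes if b not in lookup]
        if missing:
            raise KeyError(f"unknown barcodes: {missing[:5]}")
        idx = np.array([lookup[b] for b in barcodes], dtype=int)
        return CountMatrix(
            self.counts[:, idx], self.gene_ids.copy(), np.asarray(barcodes, dtype=object),
            sample_id=self.sample_id,
        )

    def to_anndata(self):
        """Droplets x genes AnnData view (the single-cell ecosystem layout)."""
        import anndata as ad

        return ad.AnnData(
            X=sp.csr_matrix(self.counts.T, dtype=np.float32),
            obs=pd.DataFrame(index=pd.Index(self.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )


def validate_qc_table(table: pd.DataFrame, required: Iterable[str] = QC_COLUMNS) -> None:
    """Raise ``ValueError`` listing any required column absent from ``table``."""
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"QC table is missing columns: {missing}")
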