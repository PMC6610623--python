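"""Readers and writers for the formats the pipeline touches.

Two count-matrix dialects are supported, matching the two droplet platforms
in common use:

* dense DGE: tab-separated text, first column gene symbols, first row droplet
  barcodes, integer body (Drop-seq convention, genes in rows);
* Matrix Market triplets (``matrix.mtx``) with ``barcodes.tsv`` and
  ``features.tsv``/``genes.tsv`` sidecars (10x convention, features in rows).

Both orientations already place genes in rows, which is the internal layout;
a file whose dimensions do not match its sidecars is rejected rather than
silently transposed.  Gzip-compressed inputs are accepted transparently.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import CountMatrix, GeneSet, QC_COLUMNS, validate_qc_table

__all__ = [
    "DGEParseError",
    "read_dense_dge",
    "write_dense_dge",
    "read_mtx",
    "write_mtx",
    "load_gene_set",
    "write_qc_table",
    "read_qc_table",
]

PathLike = Union[str, Path]


class DGEParseError(ValueError):
    """A count-matrix file violated the format contract."""


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# dense DGE
# ---------------------------------------------------------------------------

def read_dense_dge(path: PathLike, sample_id: str | None = None) -> CountMatrix:
    """Read a dense tab-separated DGE file (genes in rows, barcodes in columns).

    Raises :class:`DGEParseError` naming the offending row/column for
    malformed headers, duplicate labels, or non-integer/negative entries.
    """
    path = Path(path)
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise DGEParseError(f"{path}: empty file (no header)")
        fields = header.rstrip("\n").split("\t")
        # Header may or may not carry a leading label for the gene column.
        body = fh.read()
    barcodes = [f for f in fields[1:] if f != ""] if len(fields) > 1 else []
    if not barcodes:
        raise DGEParseError(f"{path}: header defines no droplets")
    dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
    if dupes:
        raise DGEParseError(f"{path}: duplicated barcode(s) in header: {dupes[:5]}")
    if not body.strip():
        raise DGEParseError(f"{path}: no droplets have data (empty body, header only)")
    df = pd.read_csv(
        _io.StringIO(body), sep="\t", header=None, index_col=0,
        names=["gene"] + barcodes, dtype={0: str},
    )
    if df.shape[1] != len(barcodes):
        raise DGEParseError(
            f"{path}: body has {df.shape[1]} columns but header names {len(barcodes)} barcodes"
        )
    gene_ids = df.index.astype(str)
    dup_genes = sorted(set(gene_ids[gene_ids.duplicated()]))
    if dup_genes:
        raise DGEParseError(f"{path}: duplicated gene ID(s): {dup_genes[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise DGEParseError(f"{path}: non-numeric entries in column(s) {list(bad)[:5]}")
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise DGEParseError(
            f"{path}: negative count at gene {gene_ids[r]!r}, barcode {barcodes[c]!r}"
        )
    if not np.allclose(values, np.round(values)):
        r, c = np.argwhere(values != np.round(values))[0]
        raise DGEParseError(
            f"{path}: non-integer count at gene {gene_ids[r]!r}, barcode {barcodes[c]!r}"
        )
    return CountMatrix(
        sp.csr_matrix(values.astype(np.int64)),
        gene_ids.to_numpy(dtype=object),
        np.asarray(barcodes, dtype=object),
        sample_id=sample_id or path.name.split(".")[0],
    )


def write_dense_dge(matrix: CountMatrix, path: PathLike) -> None:
    """Write a dense tab-separated DGE file (inverse of :func:`read_dense_dge`)."""
    df = pd.DataFrame(
        matrix.counts.toarray(), index=matrix.gene_ids, columns=matrix.barcodes
    )
    df.index.name = "GENE"
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Matrix Market
# ---------------------------------------------------------------------------

def _find_sidecar(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = directory / f"{stem}{suffix}"
            if candidate.exists():
                return candidate
    raise FileNotFoundError(f"{directory}: none of {stems} found")


def read_mtx(directory: PathLike, sample_id: str | None = None) -> CountMatrix:
    """Read a 10x-style directory: ``matrix.mtx(.gz)`` + barcode/feature sidecars.

    Triplet entries sharing a coordinate are summed.  A dimension mismatch
    between the matrix header and the sidecar files is a format error.
    """
    directory = Path(directory)
    mtx_path = _find_sidecar(directory, ("matrix.mtx",))
    barcodes_path = _find_sidecar(directory, ("barcodes.tsv",))
    features_path = _find_sidecar(directory, ("features.tsv", "genes.tsv"))

    with _open_text(mtx_path, "rb") as fh:
        coo = scipy.io.mmread(fh)
    with _open_text(barcodes_path) as fh:
        barcodes = [line.split("\t")[0].strip() for line in fh if line.strip()]
    with _open_text(features_path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # 10x features.tsv: column 1 = accession, column 2 = symbol.  Gene identity
    # here is the bare symbol, so prefer the second column when present.
    gene_ids = [r[1] if len(r) > 1 else r[0] for r in rows]

    if coo.shape != (len(gene_ids), len(barcodes)):
        raise DGEParseError(
            f"{mtx_path}: matrix is {coo.shape[0]} x {coo.shape[1]} but sidecars list "
            f"{len(gene_ids)} features and {len(barcodes)} barcodes"
        )
    csr = sp.csr_matrix(coo)  # conversion sums duplicate coordinates
    return CountMatrix(
        csr, np.asarray(gene_ids, dtype=object), np.asarray(barcodes, dtype=object),
        sample_id=sample_id or directory.name,
    )


def write_mtx(matrix: CountMatrix, directory: PathLike) -> None:
    """Write ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(matrix.counts), field="integer")
    (directory / "barcodes.tsv").write_text("".join(f"{b}\n" for b in matrix.barcodes))
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.gene_ids)
    )


# ---------------------------------------------------------------------------
# gene sets & QC tables
# ---------------------------------------------------------------------------

def load_gene_set(path: PathLike, name: str | None = None) -> GeneSet:
    """Load a one-symbol-per-line gene list; blank lines and ``#`` comments ignored.

    Duplicate symbols are collapsed with a warning; an empty file is an error.
    """
    path = Path(path)
    genes: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            genes.append(token)
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            warnings.warn(f"{path}: duplicate gene symbol {g!r} collapsed", stacklevel=2)
        seen.add(g)
    if not seen:
        raise ValueError(f"{path}: gene-set file is empty")
    return GeneSet(name or path.stem, seen)


def write_qc_table(table: pd.DataFrame, path: PathLike) -> None:
    """Write a QC table as TSV with the documented fixed column order.

    Floats are written at full (round-trip) precision; raises ``ValueError``
    listing any absent metric column.
    """
    validate_qc_table(table)
    ordered = list(QC_COLUMNS) + [c for c in table.columns if c not in QC_COLUMNS]
    with _open_text(path, "wt") as fh:
        table[ordered].to_csv(fh, sep="\t", index=False)


def read_qc_table(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    validate_qc_table(table)
    return table
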