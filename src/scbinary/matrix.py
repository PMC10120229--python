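"""Count matrices, normalization, binarization and bit-packed storage.

The central object of the whole package is the detection pattern of a
gene x cell count matrix: ``zero stays zero, every non-zero count becomes
a one``.  This module provides the three matrix containers (counts,
log-normalized values, packed detection bits), readers for the common
plain-text exchange formats (Matrix Market triplets with id sidecars,
dense TSV), the shuffled-counts control, and a small bit-exact on-disk
format (BBM) for detection matrices together with storage accounting.

Conventions: genes are rows, cells are columns, indices are 0-based in
memory and 1-based only inside MTX files.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "BinaryMatrix",
    "StorageReport",
    "BBMFormatError",
    "read_counts",
    "write_counts_mtx",
    "normalize_log_cp10k",
    "binarize",
    "detection_rates",
    "shuffle_nonzeros",
    "write_bbm",
    "read_bbm",
    "storage_report",
]

# BBM header: magic, 4 reserved zero bytes, n_genes and n_cells as
# little-endian uint64 -> 24 bytes total, then one LSB-first padded byte
# row per gene.
_BBM_MAGIC = b"BBM1"
_BBM_HEADER_SIZE = 24


class BBMFormatError(ValueError):
    """Raised when a BBM file is malformed (bad magic, truncation, dims)."""


def _as_str_array(x, name: str, n: int | None = None) -> np.ndarray:
    arr = np.asarray(x, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
    return arr


def _check_unique(ids: np.ndarray, name: str) -> None:
    if len(set(ids.tolist())) != len(ids):
        raise ValueError(f"{name} contains duplicates")


@dataclass
class _AnnotatedMatrix:
    """Shared axis annotations for all three matrix flavours."""

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    sample_of_cell: np.ndarray | None = None
    condition_of_cell: np.ndarray | None = None
    celltype_of_cell: np.ndarray | None = None

    def _validate_annotations(self, n_genes: int, n_cells: int) -> None:
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids", n_genes)
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids", n_cells)
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.cell_ids, "cell_ids")
        for attr in ("sample_of_cell", "condition_of_cell", "celltype_of_cell"):
            val = getattr(self, attr)
            if val is not None:
                setattr(self, attr, _as_str_array(val, attr, n_cells))
        if self.sample_of_cell is not None and self.condition_of_cell is not None:
            df = pd.DataFrame(
                {"s": self.sample_of_cell, "c": self.condition_of_cell}
            )
            if (df.groupby("s")["c"].nunique() > 1).any():
                raise ValueError("condition must be constant within each sample")

    def _annotation_kwargs(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "cell_ids": self.cell_ids,
            "sample_of_cell": self.sample_of_cell,
            "condition_of_cell": self.condition_of_cell,
            "celltype_of_cell": self.celltype_of_cell,
        }


@dataclass
class CountMatrix(_AnnotatedMatrix):
    """Raw gene x cell counts with optional sample/condition/type labels."""

    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(np.equal(np.mod(v, 1), 0)):
                raise ValueError("counts must be integral")
            v = v.astype(np.int64)
        if v.size and v.min() < 0:
            raise ValueError("counts must be non-negative")
        self.values = v.astype(np.int64, copy=False)
        self._validate_annotations(*v.shape)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedMatrix(_AnnotatedMatrix):
    """Log CP10K values; zero iff the source count was zero."""

    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if not np.all(np.isfinite(v)):
            raise ValueError("normalized values must be finite")
        if v.size and v.min() < 0:
            raise ValueError("normalized values must be non-negative")
        self.values = v
        self._validate_annotations(*v.shape)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryMatrix(_AnnotatedMatrix):
    """Bit-packed detection matrix (gene-major, LSB-first within bytes)."""

    bits: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_genes: int = 0
    n_cells: int = 0

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        row_bytes = -(-self.n_cells // 8) if self.n_cells else 0
        if bits.shape != (self.n_genes, row_bytes):
            raise ValueError(
                f"bits shape {bits.shape} inconsistent with "
                f"{self.n_genes} genes x {self.n_cells} cells"
            )
        self.bits = bits
        self._validate_annotations(self.n_genes, self.n_cells)

    @classmethod
    def from_dense(cls, dense: np.ndarray, **annotations) -> "BinaryMatrix":
        dense = np.asarray(dense)
        if not np.isin(dense, (0, 1)).all():
            raise ValueError("dense detection matrix must be 0/1")
        n_genes, n_cells = dense.shape
        bits = np.packbits(dense.astype(np.uint8), axis=1, bitorder="little")
        return cls(bits=bits, n_genes=n_genes, n_cells=n_cells, **annotations)

    def to_dense(self) -> np.ndarray:
        """Unpack to a dense uint8 genes x cells 0/1 array."""
        if self.n_genes == 0:
            return np.zeros((0, self.n_cells), dtype=np.uint8)
        dense = np.unpackbits(self.bits, axis=1, bitorder="little")
        return dense[:, : self.n_cells]

    def __eq__(self, other) -> bool:  # bit-exact comparison
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return (
            self.n_genes == other.n_genes
            and self.n_cells == other.n_cells
            and np.array_equal(self.bits, other.bits)
        )


@dataclass(frozen=True)
class StorageReport:
    """Byte-count comparison of dense float64, sparse triplet and bit storage."""

    bytes_dense_float64: int
    bytes_sparse_triplet: int
    bytes_bitpacked: int
    fold_vs_dense: float
    fold_vs_sparse: float
    detection_rate: float


# ---------------------------------------------------------------------------
# readers / writers


def _read_id_file(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].to_numpy(dtype=object)


def read_counts(
    path: str | Path,
    format: str = "mtx",
    metadata_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from MTX (+ genes.tsv/barcodes.tsv) or dense TSV.

    MTX files use 1-based coordinates; entries absent from the file are
    zero.  Duplicate coordinates are rejected rather than summed.  A
    metadata TSV (columns cell_id, sample_id, condition, cell_type) is
    joined by cell id; unknown cell ids are an error naming the offenders.
    """
    path = Path(path)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if not scipy.sparse.issparse(mat):
            raise ValueError("expected a coordinate-format MTX file")
        coo = mat.tocoo()
        keys = coo.row.astype(np.int64) * coo.shape[1] + coo.col
        if len(np.unique(keys)) != len(keys):
            raise ValueError("duplicate coordinates in MTX file")
        data = np.asarray(coo.data)
        if np.any(np.mod(data, 1) != 0) or (data.size and data.min() < 0):
            raise ValueError("MTX values must be non-negative integers")
        values = np.asarray(coo.astype(np.int64).todense())
        gene_file = path.parent / "genes.tsv"
        barcode_file = path.parent / "barcodes.tsv"
        n_genes, n_cells = values.shape
        gene_ids = (
            _read_id_file(gene_file)
            if gene_file.exists()
            else np.array([f"g{i}" for i in range(n_genes)], dtype=object)
        )
        cell_ids = (
            _read_id_file(barcode_file)
            if barcode_file.exists()
            else np.array([f"c{i}" for i in range(n_cells)], dtype=object)
        )
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        gene_ids = df.index.to_numpy(dtype=object).astype(str)
        cell_ids = df.columns.to_numpy(dtype=object).astype(str)
    else:
        raise ValueError(f"unknown format {format!r}")

    m = CountMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if "cell_id" not in meta.columns:
            raise ValueError("metadata TSV requires a cell_id column")
        meta = meta.set_index("cell_id")
        missing = [c for c in m.cell_ids if c not in meta.index]
        if missing:
            raise ValueError(
                f"metadata missing for cells: {', '.join(map(str, missing[:10]))}"
            )
        unknown = [c for c in meta.index if c not in set(m.cell_ids.tolist())]
        if unknown:
            raise ValueError(
                f"metadata cell ids not in matrix: {', '.join(map(str, unknown[:10]))}"
            )
        aligned = meta.loc[list(m.cell_ids)]
        for col, attr in (
            ("sample_id", "sample_of_cell"),
            ("condition", "condition_of_cell"),
            ("cell_type", "celltype_of_cell"),
        ):
            if col in aligned.columns:
                setattr(m, attr, aligned[col].to_numpy(dtype=object))
        m._validate_annotations(m.n_genes, m.n_cells)
    return m


def write_counts_mtx(m: CountMatrix, directory: str | Path) -> Path:
    """Write matrix.mtx + genes.tsv/barcodes.tsv (+ metadata.tsv if labelled)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(m.values)
    scipy.io.mmwrite(directory / "matrix.mtx", sparse, field="integer")
    pd.Series(m.gene_ids).to_csv(
        directory / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(m.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )
    if m.sample_of_cell is not None or m.celltype_of_cell is not None:
        meta = pd.DataFrame({"cell_id": m.cell_ids})
        if m.sample_of_cell is not None:
            meta["sample_id"] = m.sample_of_cell
        if m.condition_of_cell is not None:
            meta["condition"] = m.condition_of_cell
        if m.celltype_of_cell is not None:
            meta["cell_type"] = m.celltype_of_cell
        meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)
    return directory / "matrix.mtx"


# ---------------------------------------------------------------------------
# transforms


def normalize_log_cp10k(m: CountMatrix) -> NormalizedMatrix:
    """ln(1 + 1e4 * count / cell_total); zeros are preserved exactly."""
    totals = m.values.sum(axis=0)
    zero_cells = np.flatnonzero(totals == 0)
    if zero_cells.size:
        ids = ", ".join(map(str, m.cell_ids[zero_cells][:10]))
        raise ValueError(f"cells with zero total count: {ids}")
    vals = np.log1p(1e4 * m.values / totals[np.newaxis, :])
    return NormalizedMatrix(values=vals, **m._annotation_kwargs())


def binarize(m: CountMatrix | NormalizedMatrix | BinaryMatrix) -> BinaryMatrix:
    """Detection indicator: 1 iff the entry is non-zero.  Idempotent."""
    if isinstance(m, BinaryMatrix):
        dense = m.to_dense()
    else:
        dense = (m.values > 0).astype(np.uint8)
    return BinaryMatrix.from_dense(dense, **m._annotation_kwargs())


def detection_rates(b: BinaryMatrix, axis: str = "gene") -> np.ndarray:
    """Fraction of detected entries per gene (across cells) or per cell."""
    if b.n_genes == 0 or b.n_cells == 0:
        raise ValueError("empty matrix")
    dense = b.to_dense()
    if axis == "gene":
        return dense.mean(axis=1)
    if axis == "cell":
        return dense.mean(axis=0)
    raise ValueError("axis must be 'gene' or 'cell'")


def shuffle_nonzeros(m: CountMatrix, seed: int) -> CountMatrix:
    """Permute each gene's non-zero counts among its detected cells.

    The detection pattern (and hence the binarized matrix) is unchanged;
    only the assignment of count magnitudes to detected cells moves.  This
    is the control showing that analyses relying on detection only are
    insensitive to count magnitudes.
    """
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    for g in range(values.shape[0]):
        nz = np.flatnonzero(values[g])
        if nz.size > 1:
            values[g, nz] = rng.permutation(values[g, nz])
    return CountMatrix(values=values, **m._annotation_kwargs())


# ---------------------------------------------------------------------------
# BBM on-disk format


def write_bbm(b: BinaryMatrix, path: str | Path, ids_sidecar: bool = True) -> Path:
    """Write the bit-packed detection matrix; bit-exact roundtrip guaranteed."""
    path = Path(path)
    header = _BBM_MAGIC + b"\x00" * 4 + struct.pack("<QQ", b.n_genes, b.n_cells)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b.bits.tobytes())
    if ids_sidecar:
        sidecar = path.with_name(path.name + ".ids.tsv")
        with open(sidecar, "w") as fh:
            for gid in b.gene_ids:
                fh.write(f"gene\t{gid}\n")
            for cid in b.cell_ids:
                fh.write(f"cell\t{cid}\n")
    return path


def read_bbm(path: str | Path) -> BinaryMatrix:
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _BBM_HEADER_SIZE or raw[:4] != _BBM_MAGIC:
        raise BBMFormatError(f"{path}: not a BBM file (bad magic)")
    n_genes, n_cells = struct.unpack("<QQ", raw[8:24])
    row_bytes = -(-n_cells // 8)
    expected = _BBM_HEADER_SIZE + n_genes * row_bytes
    if len(raw) < expected:
        raise BBMFormatError(
            f"{path}: truncated payload ({len(raw)} bytes, expected {expected})"
        )
    if len(raw) > expected:
        raise BBMFormatError(
            f"{path}: payload size does not match header dimensions"
        )
    bits = np.frombuffer(
        raw, dtype=np.uint8, offset=_BBM_HEADER_SIZE
    ).reshape(n_genes, row_bytes).copy()
    # padding bits beyond n_cells must unpack to zero
    gene_ids = np.array([f"g{i}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    sidecar = path.with_name(path.name + ".ids.tsv")
    if sidecar.exists():
        df = pd.read_csv(sidecar, sep="\t", header=None, names=["kind", "id"], dtype=str)
        g = df.loc[df["kind"] == "gene", "id"].to_numpy(dtype=object)
        c = df.loc[df["kind"] == "cell", "id"].to_numpy(dtype=object)
        if len(g) != n_genes or len(c) != n_cells:
            raise BBMFormatError(f"{sidecar}: id counts do not match dimensions")
        gene_ids, cell_ids = g, c
    return BinaryMatrix(
        bits=bits, n_genes=int(n_genes), n_cells=int(n_cells),
        gene_ids=gene_ids, cell_ids=cell_ids,
    )


def storage_report(m: CountMatrix) -> StorageReport:
    """Bytes needed as dense float64, sparse triplets, or packed bits.

    Sparse triplets are accounted as int32 row + int32 col + float32 value
    (12 bytes per stored entry); the bit representation is one bit per
    entry with byte-padded gene rows plus the 24-byte BBM header.
    """
    g, c = m.values.shape
    nnz = int(np.count_nonzero(m.values))
    dense = g * c * 8
    sparse = nnz * 12
    bitpacked = g * (-(-c // 8)) + _BBM_HEADER_SIZE
    if sparse == 0:
        warnings.warn("matrix has no non-zero entries; sparse fold undefined")
    return StorageReport(
        bytes_dense_float64=dense,
        bytes_sparse_triplet=sparse,
        bytes_bitpacked=bitpacked,
        fold_vs_dense=dense / bitpacked,
        fold_vs_sparse=sparse / bitpacked if sparse else float("nan"),
        detection_rate=nnz / (g * c) if g * c else float("nan"),
    )
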