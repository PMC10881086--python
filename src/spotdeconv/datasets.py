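"""Containers and I/O for the scRNA-seq reference and spatial datasets.

Two on-disk layouts per dataset are supported plus HDF5:

* **MTX triplet** — MatrixMarket coordinate file (1-based indices) with
  ``genes.tsv`` / ``barcodes.tsv`` sidecars; 2-column TSVs are tolerated
  and the first column is used.
* **Dense CSV** — genes as rows, first column the gene id, header row
  the cell/spot ids.
* **HDF5** — datasets ``/matrix`` (dense), ``/genes``, ``/barcodes``.

Counts are raw (UMI/read) integers. Duplicate gene symbols are collapsed
by summation on read; duplicate column ids are an error. Spot
coordinates come from a CSV/TSV with columns ``spot_id, x, y``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ReferenceDataset",
    "SpatialDataset",
    "NormalizationSpec",
    "read_counts_matrix",
    "write_counts_matrix",
    "read_coordinates",
    "harmonize_gene_space",
    "normalize",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class ReferenceDataset:
    """Annotated scRNA-seq reference: genes x cells raw counts + labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.cell_types) != len(self.cell_ids):
            raise ValueError("one cell-type label required per cell")
        if len(set(self.cell_types)) < 2:
            raise ValueError("reference must contain >= 2 distinct cell types")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids contain duplicates")

    @property
    def cell_type_order(self) -> list[str]:
        """Distinct labels in lexicographic order (the output contract)."""
        return sorted(set(self.cell_types))

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        labels = np.asarray(self.cell_types)
        return np.flatnonzero(labels == cell_type)


@dataclass
class SpatialDataset:
    """Spatial transcriptomics dataset: genes x spots counts + coordinates."""

    counts: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.spot_ids)} spots)")
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValueError("coords must be spots x 2")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("spot_ids must be unique")


@dataclass
class NormalizationSpec:
    """The shared count-transformation contract for reference and spots.

    Every column (cell, mixture or spot) is scaled to a fixed total
    (counts-per-``scale``) and, if ``log_transform``, mapped through
    log(1 + x). ``gene_space`` fixes the row order the network consumes.
    """

    gene_space: list[str]
    scale: float = 10_000.0
    log_transform: bool = True

    def to_dict(self) -> dict:
        return {"gene_space": list(self.gene_space), "scale": self.scale,
                "log_transform": self.log_transform}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(gene_space=list(d["gene_space"]), scale=float(d["scale"]),
                   log_transform=bool(d["log_transform"]))


# ---------------------------------------------------------------------------
# readers / writers


def _read_sidecar_ids(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def _collapse_duplicate_genes(matrix: np.ndarray, gene_ids: list[str]):
    """Sum rows sharing a gene symbol, keeping first-occurrence order."""
    if len(set(gene_ids)) == len(gene_ids):
        return matrix, list(gene_ids)
    order: dict[str, int] = {}
    for g in gene_ids:
        if g not in order:
            order[g] = len(order)
    out = np.zeros((len(order), matrix.shape[1]), dtype=matrix.dtype)
    for row, g in zip(matrix, gene_ids):
        out[order[g]] += row
    return out, list(order)


def read_counts_matrix(path, fmt: str | None = None):
    """Read a genes x columns count matrix.

    Parameters
    ----------
    path
        For ``mtx``: the directory holding ``matrix.mtx`` + sidecars, or
        the ``.mtx`` file itself. For ``csv``/``hdf5``: the file.
    fmt
        ``"mtx"``, ``"csv"`` or ``"hdf5"``; inferred from the path when
        omitted.

    Returns
    -------
    (matrix, gene_ids, column_ids)
        Dense integer array with duplicate gene rows summed.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir() or path.suffix == ".mtx":
            fmt = "mtx"
        elif path.suffix in {".h5", ".hdf5"}:
            fmt = "hdf5"
        elif path.suffix in {".csv", ".tsv"}:
            fmt = "csv"
        else:
            raise FormatError(f"cannot infer format of {path}")

    if fmt == "mtx":
        if path.is_dir():
            mtx_path = path / "matrix.mtx"
            genes_path = path / "genes.tsv"
            barcodes_path = path / "barcodes.tsv"
        else:
            mtx_path = path
            genes_path = path.with_name("genes.tsv")
            barcodes_path = path.with_name("barcodes.tsv")
        for p in (mtx_path, genes_path, barcodes_path):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX component: {p}")
        with open(mtx_path) as fh:
            first = fh.readline()
        if not first.startswith("%%MatrixMarket"):
            raise FormatError(
                f"malformed MatrixMarket header in {mtx_path}: {first.strip()!r}")
        try:
            matrix = spio.mmread(mtx_path)
        except ValueError as exc:
            raise FormatError(f"malformed MTX file {mtx_path}: {exc}") from exc
        matrix = np.asarray(sparse.coo_matrix(matrix).todense())
        gene_ids = _read_sidecar_ids(genes_path)
        column_ids = _read_sidecar_ids(barcodes_path)
        if matrix.shape != (len(gene_ids), len(column_ids)):
            raise FormatError(
                f"MTX dimensions {matrix.shape} do not match sidecars "
                f"({len(gene_ids)} genes, {len(column_ids)} barcodes)")
    elif fmt == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        raw_columns = header[1:]  # pandas mangles duplicates, so keep raw ids
        df = pd.read_csv(path, sep=sep, index_col=0)
        matrix = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        column_ids = [str(c) for c in raw_columns]
    elif fmt == "hdf5":
        with h5py.File(path, "r") as f:
            for name in ("matrix", "genes", "barcodes"):
                if name not in f:
                    raise FormatError(f"{path} missing dataset /{name}")
            matrix = f["matrix"][()]
            gene_ids = [g.decode() if isinstance(g, bytes) else str(g)
                        for g in f["genes"][()]]
            column_ids = [c.decode() if isinstance(c, bytes) else str(c)
                          for c in f["barcodes"][()]]
        if matrix.shape != (len(gene_ids), len(column_ids)):
            raise FormatError(f"HDF5 matrix shape {matrix.shape} inconsistent "
                              "with /genes and /barcodes")
    else:
        raise FormatError(f"unknown format {fmt!r}")

    if len(set(column_ids)) != len(column_ids):
        dupes = sorted({c for c in column_ids if column_ids.count(c) > 1})
        raise ValueError(f"duplicate column ids: {dupes[:5]}")
    matrix = np.asarray(np.rint(matrix), dtype=np.int64)
    matrix, gene_ids = _collapse_duplicate_genes(matrix, gene_ids)
    return matrix, gene_ids, column_ids


def write_counts_matrix(path, matrix, gene_ids, column_ids,
                        fmt: str | None = None) -> None:
    """Write a counts matrix in any supported format (round-trip safe)."""
    path = Path(path)
    matrix = np.asarray(matrix)
    if fmt is None:
        if path.suffix in {".h5", ".hdf5"}:
            fmt = "hdf5"
        elif path.suffix in {".csv", ".tsv"}:
            fmt = "csv"
        else:
            fmt = "mtx"
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(matrix))
        (path / "genes.tsv").write_text("\n".join(gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(column_ids) + "\n")
    elif fmt == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        pd.DataFrame(matrix, index=gene_ids, columns=column_ids).to_csv(
            path, sep=sep)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=matrix)
            f.create_dataset("genes", data=np.array(gene_ids, dtype="S"))
            f.create_dataset("barcodes", data=np.array(column_ids, dtype="S"))
    else:
        raise FormatError(f"unknown format {fmt!r}")


def read_coordinates(path, spot_ids: list[str] | None = None) -> np.ndarray:
    """Read a spot_id,x,y table; returns coords ordered like ``spot_ids``."""
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path} must have header columns spot_id,x,y (got {list(df.columns)})")
    df = df.set_index(df["spot_id"].astype(str))
    if spot_ids is not None:
        missing = [s for s in spot_ids if s not in df.index]
        if missing:
            raise ValueError(f"coordinates missing for spots {missing[:5]}")
        df = df.loc[spot_ids]
    return df[["x", "y"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# gene-space harmonisation and normalisation


def harmonize_gene_space(ref: ReferenceDataset, st: SpatialDataset,
                         min_counts: int = 0, min_cells_frac: float = 0.0,
                         exclude_regex: str | None = None,
                         scale: float = 10_000.0,
                         log_transform: bool = True) -> NormalizationSpec:
    """Intersect reference and spatial gene ids and filter weak genes.

    Genes kept: present in both datasets, total reference counts
    >= ``min_counts``, expressed (count > 0) in at least
    ``min_cells_frac`` of reference cells, and not matching
    ``exclude_regex`` (e.g. ``"^(MT-|RP[SL])"`` to drop mitochondrial and
    ribosomal genes). The surviving gene space is lexicographically
    sorted so it is independent of input gene order.
    """
    ref_genes = set(ref.gene_ids)
    st_genes = set(st.gene_ids)
    common = ref_genes & st_genes
    if not common:
        raise ValueError(
            "reference and spatial datasets share no genes "
            f"(reference e.g. {sorted(ref_genes)[:3]}, "
            f"spatial e.g. {sorted(st_genes)[:3]})")
    gene_index = {g: i for i, g in enumerate(ref.gene_ids)}
    counts = np.asarray(ref.counts)
    n_cells = counts.shape[1]
    keep = []
    pattern = re.compile(exclude_regex) if exclude_regex else None
    for g in sorted(common):
        if pattern is not None and pattern.search(g):
            continue
        row = counts[gene_index[g]]
        if row.sum() < min_counts:
            continue
        if n_cells and (row > 0).sum() / n_cells < min_cells_frac:
            continue
        keep.append(g)
    if not keep:
        raise ValueError("no genes survive filtering; relax min_counts / "
                         "min_cells_frac")
    return NormalizationSpec(gene_space=keep, scale=scale,
                             log_transform=log_transform)


def normalize(matrix, spec: NormalizationSpec) -> np.ndarray:
    """Scale each column to total ``spec.scale`` then apply log1p.

    ``matrix`` rows must already be ordered as ``spec.gene_space``.
    All-zero columns stay zero. Idempotent on column sums: renormalising
    an already scaled (pre-log) matrix is a no-op.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(spec.gene_space):
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but gene_space has "
            f"{len(spec.gene_space)} genes")
    totals = matrix.sum(axis=0)
    factors = np.divide(spec.scale, totals, out=np.zeros_like(totals),
                        where=totals > 0)
    out = matrix * factors[np.newaxis, :]
    if spec.log_transform:
        out = np.log1p(out)
    return out


def subset_to_gene_space(matrix, gene_ids: list[str],
                         gene_space: list[str]) -> np.ndarray:
    """Reindex rows to ``gene_space``, zero-filling missing genes."""
    matrix = np.asarray(matrix)
    index = {g: i for i, g in enumerate(gene_ids)}
    out = np.zeros((len(gene_space), matrix.shape[1]), dtype=matrix.dtype)
    for j, g in enumerate(gene_space):
        i = index.get(g)
        if i is not None:
            out[j] = matrix[i]
    return out
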