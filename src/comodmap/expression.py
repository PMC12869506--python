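"""Count-matrix I/O, the total-count gene filter and cell-type selection.

The central container is :class:`ExpressionMatrix`: a dense genes x cells
non-negative count matrix with unique gene and cell identifiers and one
cell-type label per cell.  Three on-disk renditions are supported and
round-trip exactly:

* ``mtx``  — MatrixMarket coordinate file plus two TSV sidecars
  (``<stem>.genes.tsv`` with one gene id per line, ``<stem>.cells.tsv``
  with ``cell_id<TAB>cell_type`` per line);
* ``tsv``  — a single dense TSV, genes as rows, with a two-row header
  (cell ids, then cell types);
* ``loom`` — the HDF5 loom layout (``/matrix`` genes x cells,
  ``row_attrs/Gene``, ``col_attrs/CellID`` and ``col_attrs/cell_type``).

The gene filter keeps candidate genes whose total count across the cells in
scope meets a threshold (default 5000, inclusive).  The pipeline applies it
to the full dataset before any cell-type subsetting, so the retained gene
list does not depend on which neuronal populations are selected afterwards.
The filter operates on whatever values the matrix holds — raw or normalized
counts alike; this package never normalizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "ExpressionMatrix",
    "FilterParams",
    "read_expression",
    "write_expression",
    "filter_genes_by_total_counts",
    "select_cells_by_type",
    "default_neuronal_cell_types",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells count matrix with per-cell type labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_types = [str(t) for t in self.cell_types]
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(self.cell_types) != n_cells:
            raise FormatError("one cell_type label required per cell")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell ids")
        if np.any(self.counts < 0):
            raise DataError("negative values in count matrix")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            self.counts[idx, :], list(genes), list(self.cell_ids), list(self.cell_types)
        )


@dataclass
class FilterParams:
    """Parameters of the total-count gene filter.

    ``min_total_counts`` defaults to 5000; ``inclusive`` controls whether the
    threshold itself passes (>=, the default) or not (>).  ``scope`` records
    whether the filter is meant to run on the full dataset (before cell-type
    selection) or only on the currently selected cells; the pipeline honours
    it when ordering stages.
    """

    min_total_counts: float = 5000.0
    inclusive: bool = True
    scope: Literal["full_dataset", "selected_cells"] = "full_dataset"

    def __post_init__(self) -> None:
        if self.min_total_counts < 0:
            raise ParameterError("min_total_counts must be >= 0")
        if self.scope not in ("full_dataset", "selected_cells"):
            raise ParameterError(
                f"scope must be 'full_dataset' or 'selected_cells', got {self.scope!r}"
            )


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.tsv"), stem.with_suffix(".cells.tsv")


def write_expression(
    mat: ExpressionMatrix, path: str | Path, format: Literal["mtx", "tsv", "loom"] = "mtx"
) -> None:
    """Serialize ``mat`` in the named dialect (see module docstring)."""
    path = Path(path)
    if format == "mtx":
        sparse = scipy.sparse.coo_matrix(mat.counts)
        scipy.io.mmwrite(str(path), sparse)
        genes_path, cells_path = _sidecar_paths(path)
        genes_path.write_text("".join(f"{g}\n" for g in mat.gene_ids))
        cells_path.write_text(
            "".join(f"{c}\t{t}\n" for c, t in zip(mat.cell_ids, mat.cell_types))
        )
    elif format == "tsv":
        columns = pd.MultiIndex.from_arrays(
            [mat.cell_ids, mat.cell_types], names=["cell_id", "cell_type"]
        )
        frame = pd.DataFrame(mat.counts, index=mat.gene_ids, columns=columns)
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t")
    elif format == "loom":
        import h5py

        str_dt = h5py.string_dtype(encoding="utf-8")
        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=mat.counts)
            row = f.create_group("row_attrs")
            row.create_dataset("Gene", data=mat.gene_ids, dtype=str_dt)
            col = f.create_group("col_attrs")
            col.create_dataset("CellID", data=mat.cell_ids, dtype=str_dt)
            col.create_dataset("cell_type", data=mat.cell_types, dtype=str_dt)
    else:
        raise ParameterError(f"unknown format {format!r}")


def read_expression(
    path: str | Path, format: Literal["mtx", "tsv", "loom"] = "mtx"
) -> ExpressionMatrix:
    """Read a count matrix written by :func:`write_expression`.

    Raises :class:`FormatError` on dimension mismatches between the matrix
    and its id sidecars, and on duplicated identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"expression file not found: {path}")
    if format == "mtx":
        raw = scipy.io.mmread(str(path))
        counts = np.asarray(raw.todense() if scipy.sparse.issparse(raw) else raw)
        genes_path, cells_path = _sidecar_paths(path)
        if not genes_path.exists() or not cells_path.exists():
            raise FormatError(
                f"missing sidecar files {genes_path.name} / {cells_path.name}"
            )
        gene_ids = genes_path.read_text().splitlines()
        cells = [line.split("\t") for line in cells_path.read_text().splitlines()]
        if any(len(c) != 2 for c in cells):
            raise FormatError("cell sidecar must have cell_id<TAB>cell_type per line")
        cell_ids = [c[0] for c in cells]
        cell_types = [c[1] for c in cells]
        return ExpressionMatrix(counts, gene_ids, cell_ids, cell_types)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
        cell_ids = [c[0] for c in frame.columns]
        cell_types = [c[1] for c in frame.columns]
        return ExpressionMatrix(
            frame.to_numpy(), list(frame.index), cell_ids, cell_types
        )
    if format == "loom":
        import h5py

        with h5py.File(path, "r") as f:
            if "matrix" not in f:
                raise FormatError("loom file lacks a /matrix dataset")
            counts = f["matrix"][:]
            try:
                gene_ids = [g.decode() if isinstance(g, bytes) else str(g)
                            for g in f["row_attrs/Gene"][:]]
                cell_ids = [c.decode() if isinstance(c, bytes) else str(c)
                            for c in f["col_attrs/CellID"][:]]
                cell_types = [t.decode() if isinstance(t, bytes) else str(t)
                              for t in f["col_attrs/cell_type"][:]]
            except KeyError as exc:
                raise FormatError(f"loom file lacks required attribute: {exc}") from exc
        return ExpressionMatrix(counts, gene_ids, cell_ids, cell_types)
    raise ParameterError(f"unknown format {format!r}")


def filter_genes_by_total_counts(
    mat: ExpressionMatrix,
    candidates: Sequence[str],
    params: FilterParams | None = None,
) -> list[str]:
    """Return the candidate genes whose total count passes the threshold.

    Candidates absent from the matrix are dropped with a warning; input order
    is preserved.  Totals are summed over all cells of ``mat`` — callers
    wanting the filter on a cell subset pass the subsetted matrix.
    """
    params = params or FilterParams()
    present = set(mat.gene_ids)
    missing = [g for g in candidates if g not in present]
    if missing:
        warnings.warn(
            f"{len(missing)} candidate gene(s) absent from the matrix and dropped: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    kept_candidates = [g for g in candidates if g in present]
    idx = mat.gene_index(kept_candidates)
    totals = mat.counts[idx, :].sum(axis=1)
    if params.inclusive:
        mask = totals >= params.min_total_counts
    else:
        mask = totals > params.min_total_counts
    return [g for g, ok in zip(kept_candidates, mask) if ok]


def select_cells_by_type(
    mat: ExpressionMatrix,
    include: Sequence[str] | None = None,
    exclude: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Subset cells by type label (case-sensitive); the gene axis is untouched.

    Exactly one of ``include`` / ``exclude`` must be given.  Labels listed but
    absent from the data produce a warning, not an error; a selection that
    leaves no cells raises :class:`DataError`.
    """
    if (include is None) == (exclude is None):
        raise ParameterError("give exactly one of include= or exclude=")
    listed = set(include if include is not None else exclude)
    present = set(mat.cell_types)
    absent = sorted(listed - present)
    if absent:
        warnings.warn(
            f"{len(absent)} listed cell type(s) absent from the data: {absent[:5]}"
            f"{'...' if len(absent) > 5 else ''}",
            stacklevel=2,
        )
    types = np.asarray(mat.cell_types)
    if include is not None:
        mask = np.isin(types, list(listed))
    else:
        mask = ~np.isin(types, list(listed))
    if not mask.any():
        raise DataError("cell-type selection removed every cell")
    return ExpressionMatrix(
        mat.counts[:, mask],
        list(mat.gene_ids),
        [c for c, ok in zip(mat.cell_ids, mask) if ok],
        [t for t, ok in zip(mat.cell_types, mask) if ok],
    )


def default_neuronal_cell_types() -> list[str]:
    """The 45 neuronal cell-type labels selected for the co-expression analysis."""
    text = (
        resources.files("comodmap").joinpath("data/neuronal_cell_types.txt").read_text()
    )
    return [line for line in text.splitlines() if line.strip()]
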