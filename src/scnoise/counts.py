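"""Count-matrix I/O, validation, and dataset filtering.

All matrices are kept in genes x cells orientation internally; functions
reading from disk normalize the orientation at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)


class CountMatrixError(ValueError):
    """Raised for malformed or inconsistent count-matrix inputs."""


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells, with feature and barcode identifiers.

    Attributes
    ----------
    counts
        Dense nonnegative integer array of shape ``(n_genes, n_cells)``.
    gene_ids
        Unique feature identifiers, one per row.
    cell_ids
        Unique barcodes, one per column.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    total_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountMatrixError("counts must be a 2-D genes x cells array")
        if np.any(self.counts < 0):
            raise CountMatrixError("counts contain negative entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise CountMatrixError("counts contain non-integer entries")
            self.counts = np.round(self.counts).astype(np.int64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.gene_ids) != self.counts.shape[0]:
            raise CountMatrixError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[0]} matrix rows"
            )
        if len(self.cell_ids) != self.counts.shape[1]:
            raise CountMatrixError(
                f"{len(self.cell_ids)} cell ids for {self.counts.shape[1]} matrix columns"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise CountMatrixError(f"duplicate {name} identifiers")
        self.total_counts = self.counts.sum(axis=0).astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset(self, gene_mask: np.ndarray | None = None, cell_mask: np.ndarray | None = None) -> "CountMatrix":
        """Return a new matrix restricted to the given boolean masks."""
        counts = self.counts
        gene_ids = self.gene_ids
        cell_ids = self.cell_ids
        if gene_mask is not None:
            counts = counts[gene_mask, :]
            gene_ids = gene_ids[gene_mask]
        if cell_mask is not None:
            counts = counts[:, cell_mask]
            cell_ids = cell_ids[cell_mask]
        return CountMatrix(counts, gene_ids, cell_ids)


def _read_id_file(path: Path, expected: int, what: str) -> np.ndarray:
    if not path.exists():
        raise CountMatrixError(f"missing {what} file: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    if len(ids) != expected:
        raise CountMatrixError(
            f"{what} file {path} has {len(ids)} rows but the matrix declares {expected}"
        )
    return _dedupe_ids(ids, what)


def _dedupe_ids(ids: np.ndarray, what: str) -> np.ndarray:
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for x in ids:
        if x in seen:
            seen[x] += 1
            out.append(f"{x}.{seen[x]}")
            n_dup += 1
        else:
            seen[x] = 0
            out.append(x)
    if n_dup:
        logger.warning("%d duplicate %s identifiers disambiguated by suffixing", n_dup, what)
    return np.asarray(out, dtype=object)


def read_counts(path: str | Path, format: str = "mtx_dir") -> CountMatrix:
    """Read a UMI count matrix from disk.

    Parameters
    ----------
    path
        For ``mtx_dir``: a directory containing ``matrix.mtx``,
        ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``.
        For ``tsv``: a dense TSV with gene rows and a header of cell ids.
    format
        ``"mtx_dir"`` or ``"tsv"``.
    """
    path = Path(path)
    if not path.exists():
        raise CountMatrixError(f"input path does not exist: {path}")
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    if format == "tsv":
        return _read_dense_tsv(path)
    raise CountMatrixError(f"unknown format {format!r}; expected 'mtx_dir' or 'tsv'")


def _read_mtx_dir(path: Path) -> CountMatrix:
    mtx_path = None
    for cand in ("matrix.mtx", "counts.mtx"):
        if (path / cand).exists():
            mtx_path = path / cand
            break
    if mtx_path is None:
        raise CountMatrixError(f"no matrix.mtx found in {path}")
    try:
        mat = spio.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise CountMatrixError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise CountMatrixError(f"non-integer entries in {mtx_path}")
    counts = np.asarray(mat.todense()).astype(np.int64)

    feat_path = path / "features.tsv"
    if not feat_path.exists():
        feat_path = path / "genes.tsv"
    gene_ids = _read_id_file(feat_path, counts.shape[0], "features")
    cell_ids = _read_id_file(path / "barcodes.tsv", counts.shape[1], "barcodes")
    return CountMatrix(counts, gene_ids, cell_ids)


def _read_dense_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        counts = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise CountMatrixError(f"non-integer entries in {path}: {exc}") from exc
    return CountMatrix(
        counts,
        _dedupe_ids(df.index.to_numpy(dtype=object), "gene"),
        _dedupe_ids(df.columns.to_numpy(dtype=object), "cell"),
    )


def write_counts(cm: CountMatrix, path: str | Path, format: str = "mtx_dir") -> None:
    """Write a count matrix as a MatrixMarket directory or a dense TSV."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(cm.counts), field="integer")
        pd.Series(cm.gene_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(cm.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "tsv":
        pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids).to_csv(path, sep="\t")
    else:
        raise CountMatrixError(f"unknown format {format!r}")


def filter_dataset(
    cm: CountMatrix,
    min_cell_total: int = 1000,
    min_gene_count: int = 5,
    min_gene_cells: int = 5,
    exclude_patterns: Sequence[str] = (),
    exclude_correlated: bool = False,
    corr_threshold: float = 0.65,
) -> CountMatrix:
    """Apply the standard dataset filters.

    Filtering order: low-total cells are removed first, then genes matching
    ``exclude_patterns`` (optionally together with genes correlated to them
    above ``corr_threshold``, Pearson on log1p counts), then genes failing the
    abundance rule (at least ``min_gene_count`` counts in at least
    ``min_gene_cells`` cells; thresholds inclusive).
    """
    cell_mask = cm.total_counts >= min_cell_total
    if not cell_mask.any():
        raise CountMatrixError(
            f"no cell reaches min_cell_total={min_cell_total}; max total is {cm.total_counts.max()}"
        )
    cm = cm.subset(cell_mask=cell_mask)

    excluded = np.zeros(cm.n_genes, dtype=bool)
    if exclude_patterns:
        compiled = [re.compile(p) for p in exclude_patterns]
        for i, g in enumerate(cm.gene_ids):
            if any(p.search(str(g)) for p in compiled):
                excluded[i] = True
    if exclude_correlated and excluded.any() and (~excluded).any():
        logx = np.log1p(cm.counts.astype(float))
        ex = logx[excluded]
        keep = logx[~excluded]

        def _center(a: np.ndarray) -> np.ndarray:
            a = a - a.mean(axis=1, keepdims=True)
            norm = np.sqrt((a**2).sum(axis=1))
            norm[norm == 0] = 1.0
            return a / norm[:, None]

        corr = _center(keep) @ _center(ex).T
        corr_hit = np.zeros(cm.n_genes, dtype=bool)
        corr_hit[~excluded] = np.abs(corr).max(axis=1) > corr_threshold
        excluded |= corr_hit
    cm = cm.subset(gene_mask=~excluded)

    gene_mask = (cm.counts >= min_gene_count).sum(axis=1) >= min_gene_cells
    if not gene_mask.any():
        raise CountMatrixError("gene abundance filter removed all genes")
    out = cm.subset(gene_mask=gene_mask)
    logger.info(
        "filter_dataset: kept %d/%d genes, %d cells", out.n_genes, len(excluded), out.n_cells
    )
    return out
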