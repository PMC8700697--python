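"""Count-matrix container, MatrixMarket I/O, cell QC and normalization.

Matrices are gene-rows x cell-columns throughout the package. On disk a
count matrix is the 10x-style triplet: ``matrix.mtx`` (MatrixMarket
coordinate integer), ``genes.tsv`` and ``barcodes.tsv`` (one identifier
per line). Ids are authoritative; all integer indexing is internal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import EmptyResultError, FormatError

__all__ = [
    "CountMatrix", "NormalizedMatrix", "QCReport",
    "read_counts", "write_counts", "qc_filter", "normalize",
]

log = logging.getLogger(__name__)


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Gene x cell non-negative integer transcript counts.

    ``counts`` may be dense ``ndarray`` or any scipy sparse matrix; it is
    stored as CSR so iteration over nonzeros never densifies.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self):
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        c = self.counts
        if not sp.issparse(c):
            c = sp.csr_matrix(np.asarray(c))
        else:
            c = c.tocsr()
        if c.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {c.shape} != "
                f"({len(self.gene_ids)} genes, {len(self.cell_ids)} cells)")
        if c.nnz and c.data.min() < 0:
            raise FormatError("negative count encountered")
        if c.nnz and not np.allclose(c.data, np.round(c.data)):
            bad = c.data[~np.isclose(c.data, np.round(c.data))][0]
            raise FormatError(f"non-integer count encountered: {bad}")
        c.data = np.round(c.data).astype(np.int64)
        self.counts = c

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total_counts(self) -> np.ndarray:
        """Per-cell library size."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with at least one count."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in keep],
            counts=self.counts[:, keep],
        )

    def gene_index(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise FormatError(f"genes not in matrix: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)


@dataclass
class NormalizedMatrix:
    """Gene x cell log-normalized expression.

    value(g, c) = log(count(g, c) / total(c) * scale_factor + pseudocount)
    with the default pseudocount 1, so zero counts map exactly to 0 and
    the sparse structure of the counts is preserved.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: sp.csr_matrix
    scale_factor: float
    pseudocount: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes) -> np.ndarray:
        return CountMatrix.gene_index(self, genes)  # same id contract

    def cell_index(self, cells) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in pos]
        if missing:
            raise FormatError(f"cells not in matrix: {missing[:5]}")
        return np.array([pos[c] for c in cells], dtype=int)

    def dense(self) -> np.ndarray:
        return self.values.toarray()


@dataclass
class QCReport:
    """Per-cell QC metrics and the thresholds that produced them."""

    table: pd.DataFrame  # cell_id, total_counts, detected_genes, pass, reason
    min_counts: int
    min_genes: int

    @property
    def n_removed(self) -> int:
        return int((~self.table["pass"]).sum())


def _read_ids(path: str | Path, what: str) -> list[str]:
    ids = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s:
            # tolerate extra TSV columns (10x genes.tsv has id<TAB>symbol)
            ids.append(s.split("\t")[0])
    _check_unique(ids, what)
    return ids


def read_counts(path_mtx: str | Path, path_genes: str | Path,
                path_cells: str | Path) -> CountMatrix:
    """Read a MatrixMarket counts triplet into a CountMatrix.

    Raises :class:`FormatError` when the mtx dimensions disagree with the
    id files, ids are duplicated, or entries are non-integer/negative.
    """
    genes = _read_ids(path_genes, "gene")
    cells = _read_ids(path_cells, "cell")
    try:
        m = scipy.io.mmread(str(path_mtx))
    except Exception as e:  # malformed mtx header/body
        raise FormatError(f"cannot parse {path_mtx}: {e}") from e
    m = sp.csr_matrix(m)
    if m.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{path_mtx} declares {m.shape[0]} x {m.shape[1]} but id files "
            f"list {len(genes)} genes and {len(cells)} cells")
    return CountMatrix(gene_ids=genes, cell_ids=cells, counts=m)


def write_counts(m: CountMatrix, directory: str | Path,
                 mtx_name: str = "matrix.mtx") -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv under `directory`."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / mtx_name), m.counts.tocoo(), field="integer")
    (d / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (d / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))


def qc_filter(m: CountMatrix, min_counts: int = 1000, min_genes: int = 200
              ) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells by library size and gene detection.

    A cell passes iff total counts >= ``min_counts`` AND detected genes
    >= ``min_genes``. The report lists every cell with its metrics and,
    for failures, the reason. The gene set is never altered. Raises
    :class:`EmptyResultError` if no cell survives.
    """
    if min_counts < 0 or min_genes < 0:
        raise FormatError("QC thresholds must be non-negative")
    totals = m.total_counts()
    detected = m.genes_detected()
    ok_counts = totals >= min_counts
    ok_genes = detected >= min_genes
    passed = ok_counts & ok_genes

    reasons = np.where(
        passed, "",
        np.where(~ok_counts & ~ok_genes, "low_counts;low_genes",
                 np.where(~ok_counts, "low_counts", "low_genes")))
    report = QCReport(
        table=pd.DataFrame({
            "cell_id": m.cell_ids,
            "total_counts": totals.astype(int),
            "detected_genes": detected.astype(int),
            "pass": passed,
            "reason": reasons,
        }),
        min_counts=min_counts, min_genes=min_genes)
    if not passed.any():
        raise EmptyResultError(
            f"QC removed all {len(m.cell_ids)} cells "
            f"(min_counts={min_counts}, min_genes={min_genes})")
    if report.n_removed:
        log.info("QC removed %d/%d cells", report.n_removed, len(m.cell_ids))
    return m.subset_cells(passed), report


def normalize(m: CountMatrix, scale_factor: float = 10_000.0,
              pseudocount: float = 1.0) -> NormalizedMatrix:
    """Library-size normalize and log-transform.

    value(g,c) = log(counts(g,c)/total(c) * scale_factor + pseudocount).
    With pseudocount 1 a zero count maps exactly to log(1) = 0, so the
    result keeps the counts' sparsity. Cells with zero total counts are
    rejected (run :func:`qc_filter` first).
    """
    if scale_factor <= 0 or pseudocount <= 0:
        raise FormatError("scale_factor and pseudocount must be positive")
    totals = m.total_counts()
    if (totals == 0).any():
        bad = [m.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise EmptyResultError(
            f"cells with zero total counts (e.g. {bad}); apply qc_filter "
            "with min_counts >= 1 first")
    v = m.counts.tocoo().astype(float)
    scaled = v.data / totals[v.col] * scale_factor
    if pseudocount == 1.0:
        data = np.log1p(scaled)
    else:
        # pseudocount != 1 breaks zero-preservation; densify explicitly
        dense = (m.counts.toarray() / totals[None, :]) * scale_factor
        return NormalizedMatrix(
            gene_ids=list(m.gene_ids), cell_ids=list(m.cell_ids),
            values=sp.csr_matrix(np.log(dense + pseudocount)),
            scale_factor=scale_factor, pseudocount=pseudocount)
    out = sp.coo_matrix((data, (v.row, v.col)), shape=m.counts.shape)
    return NormalizedMatrix(
        gene_ids=list(m.gene_ids), cell_ids=list(m.cell_ids),
        values=out.tocsr(), scale_factor=scale_factor,
        pseudocount=pseudocount)
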