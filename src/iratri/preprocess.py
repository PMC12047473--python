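"""Cell-level quality control and CP10K log normalization.

The QC convention follows common scRNA-seq practice: a cell is retained iff

* ``min_genes <= detected genes <= max_genes`` (detected = count > 0), and
* mitochondrial fraction (genes matching a prefix, default ``MT-``)
  ``<= max_mito_fraction``, computed on raw counts.

Normalization is counts-per-10,000 followed by natural log(1 + x), the
standard Seurat-style ``LogNormalize`` with scale factor 10,000.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

SCALE_FACTOR = 10_000.0


@dataclass
class CountMatrix:
    """Sparse genes x cells integer counts with an optional normalized layer."""

    genes: np.ndarray
    cells: np.ndarray
    counts: sparse.csr_matrix
    normalized: sparse.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.cells = np.asarray(self.cells)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if (self.counts.data < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_index(self, barcodes) -> np.ndarray:
        """Positions of *barcodes* in the cell axis (raises on unknowns)."""
        lookup = {b: i for i, b in enumerate(self.cells)}
        try:
            return np.array([lookup[b] for b in barcodes], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"barcode {exc.args[0]!r} not in matrix") from None

    def subset_cells(self, barcodes) -> "CountMatrix":
        idx = self.cell_index(barcodes)
        return CountMatrix(
            genes=self.genes,
            cells=self.cells[idx],
            counts=self.counts[:, idx].tocsr(),
            normalized=None if self.normalized is None else self.normalized[:, idx].tocsr(),
        )


@dataclass
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 6000
    max_mito_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


def qc_filter_cells(
    matrix: CountMatrix,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = "MT-",
) -> tuple[np.ndarray, dict]:
    """Apply per-cell QC; return (retained barcodes, report).

    A cell is removed iff detected genes < ``min_genes``, detected genes
    > ``max_genes``, or mitochondrial fraction > ``max_mito_fraction``.
    Boundary values are retained. If no gene matches *mito_prefix* the
    mitochondrial criterion is skipped with a warning.
    """
    thresholds = thresholds or QCThresholds()
    csc = matrix.counts.tocsc()
    detected = np.diff(csc.indptr)  # nonzero entries per cell
    totals = np.asarray(csc.sum(axis=0)).ravel()

    mito_mask = np.array([str(g).startswith(mito_prefix) for g in matrix.genes])
    if mito_mask.any():
        mito_counts = np.asarray(csc[mito_mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        fail_mito = mito_frac > thresholds.max_mito_fraction
    else:
        warnings.warn(
            f"no genes matched mitochondrial prefix {mito_prefix!r}; "
            "mitochondrial criterion skipped",
            stacklevel=2,
        )
        logger.warning("mito criterion skipped: no genes with prefix %r", mito_prefix)
        fail_mito = np.zeros(matrix.n_cells, dtype=bool)

    fail_low = detected < thresholds.min_genes
    fail_high = detected > thresholds.max_genes
    keep = ~(fail_low | fail_high | fail_mito)
    report = {
        "n_input": int(matrix.n_cells),
        "n_retained": int(keep.sum()),
        "removed_low_genes": int(fail_low.sum()),
        "removed_high_genes": int(fail_high.sum()),
        "removed_mito": int(fail_mito.sum()),
        "mito_criterion_applied": bool(mito_mask.any()),
        "thresholds": {
            "min_genes": thresholds.min_genes,
            "max_genes": thresholds.max_genes,
            "max_mito_fraction": thresholds.max_mito_fraction,
        },
    }
    return matrix.cells[keep], report


def normalize_log1p_cp10k(matrix: CountMatrix) -> CountMatrix:
    """Attach the ln(1 + 10,000 * count / cell_total) layer.

    Zero-total cells are an error (they should have been removed by QC);
    the first offending barcode is named. Sparsity is preserved: zero
    counts map to exactly 0.
    """
    csc = matrix.counts.tocsc().astype(np.float64)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = matrix.cells[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total count; run QC first")
    scaled = csc @ sparse.diags(SCALE_FACTOR / totals)
    scaled.data = np.log1p(scaled.data)
    return replace(matrix, normalized=scaled.tocsr())
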