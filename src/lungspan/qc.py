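"""Cell/gene quality filtering and CP10K log normalization.

Filtering order is cells first, then genes: cells with fewer than
``min_features`` expressed genes or with mitochondrial percentage above
``max_percent_mt`` are removed, after which genes with total UMI not
strictly greater than ``min_gene_umi`` are dropped. Normalization scales
each remaining cell to 10,000 transcripts and applies the natural log:
``value = ln(1 + 1e4 * count / total)``, with cell totals computed on the
post-filter gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellAnnotation, CountMatrix, NormalizedMatrix

log = logging.getLogger("lungspan")

__all__ = ["QCThresholds", "QCReport", "qc_filter", "normalize"]


@dataclass(frozen=True)
class QCThresholds:
    min_features: int = 200      # cells with n_feature < this are removed
    max_percent_mt: float = 10.0  # cells with percent_mt > this are removed
    min_gene_umi: int = 5        # genes kept only if total UMI > this

    def __post_init__(self) -> None:
        if self.min_features < 0:
            raise ValueError("min_features must be >= 0")
        if not 0 <= self.max_percent_mt <= 100:
            raise ValueError("max_percent_mt must be in [0, 100]")


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_low_features: int
    n_cells_high_mito: int
    n_cells_out: int
    n_genes_in: int
    n_genes_low_umi: int
    n_genes_out: int
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def frame(self) -> pd.DataFrame:
        rows = [
            ("cells_in", self.n_cells_in),
            ("cells_removed_low_features", self.n_cells_low_features),
            ("cells_removed_high_mito", self.n_cells_high_mito),
            ("cells_out", self.n_cells_out),
            ("genes_in", self.n_genes_in),
            ("genes_removed_low_umi", self.n_genes_low_umi),
            ("genes_out", self.n_genes_out),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def qc_filter(
    counts: CountMatrix,
    ann: CellAnnotation,
    thr: QCThresholds = QCThresholds(),
) -> tuple[CountMatrix, CellAnnotation, QCReport]:
    """Apply the cell filter, then the gene filter.

    Cell removal rule: ``n_feature < min_features`` OR
    ``percent_mt > max_percent_mt`` (the boundary percent is kept).
    Gene removal rule: total UMI <= ``min_gene_umi`` over the retained cells.
    """
    if not ann.matches(counts):
        raise ValueError("annotation does not cover the count matrix cells")

    nf = ann.table["n_feature"].to_numpy()
    pm = ann.table["percent_mt"].to_numpy()
    low_feat = nf < thr.min_features
    high_mito = pm > thr.max_percent_mt
    keep_cells = ~(low_feat | high_mito)
    if not keep_cells.any():
        raise ValueError("empty after QC: every cell was filtered out")

    filtered = counts.subset(cell_mask=keep_cells)
    gene_totals = filtered.total_counts_per_gene()
    keep_genes = gene_totals > thr.min_gene_umi
    out = filtered.subset(gene_mask=keep_genes)
    ann_out = ann.loc(out.cells)

    report = QCReport(
        n_cells_in=counts.n_cells,
        n_cells_low_features=int(low_feat.sum()),
        n_cells_high_mito=int((high_mito & ~low_feat).sum()),
        n_cells_out=out.n_cells,
        n_genes_in=counts.n_genes,
        n_genes_low_umi=int((~keep_genes).sum()),
        n_genes_out=out.n_genes,
        thresholds=thr,
    )
    log.info(
        "QC: %d/%d cells kept, %d/%d genes kept",
        report.n_cells_out, report.n_cells_in,
        report.n_genes_out, report.n_genes_in,
    )
    return out, ann_out, report


def normalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """CP10K log normalization: ``ln(1 + scale * count / cell_total)``.

    Totals are taken over the genes of the matrix as given (i.e. the
    post-QC universe when called after :func:`qc_filter`).
    """
    totals = counts.total_counts_per_cell().astype(float)
    if np.any(totals <= 0):
        bad = [c for c, t in zip(counts.cells, totals) if t <= 0]
        raise ValueError(f"cell(s) with zero total counts: {bad[:3]}")
    dense = counts.counts.toarray().astype(float)
    values = np.log1p(scale * dense / totals[np.newaxis, :])
    return NormalizedMatrix(list(counts.genes), list(counts.cells), values)
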