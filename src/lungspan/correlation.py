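"""Score-gated Pearson correlation between a gene and signature scores.

The cell subset is the conjunction gate used for the focal-gene analysis:
cells belonging to the requested age groups (default T4 and T5, the two
adult groups) whose **every** supplied signature score is strictly greater
than the gate (default 0.01). Pearson r is computed between the gene's
log-normalized expression and each score over that subset, with the
two-sided p from t = r * sqrt((n - 2) / (1 - r^2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CellAnnotation, NormalizedMatrix
from .scoring import ScoreResult

log = logging.getLogger("lungspan")

__all__ = ["CorrelationResult", "score_gene_correlation", "gated_cells"]


@dataclass
class CorrelationResult:
    gene: str
    score_name: str
    r: float
    p: float
    n_cells: int
    gate: str

    def frame_row(self) -> dict:
        return {
            "gene": self.gene, "score_name": self.score_name,
            "r": self.r, "p": self.p, "n_cells": self.n_cells,
            "gate": self.gate,
        }


def gated_cells(
    ann: CellAnnotation,
    scores: Sequence[ScoreResult],
    groups: Iterable[str] = ("T4", "T5"),
    score_gate: float = 0.01,
) -> list[str]:
    """Barcodes in ``groups`` with every score strictly above the gate."""
    groups = set(groups)
    in_group = ann.table["group"].astype(str).isin(groups)
    keep = in_group.copy()
    for sc in scores:
        s = sc.series().reindex(ann.table.index)
        if s.isna().any():
            raise ValueError(
                f"score {sc.name!r} does not cover every annotated cell")
        keep &= s > score_gate
    return list(ann.table.index[keep])


def score_gene_correlation(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    gene: str,
    scores: Sequence[ScoreResult],
    groups: Iterable[str] = ("T4", "T5"),
    score_gate: float = 0.01,
) -> list[CorrelationResult]:
    """Pearson r of ``gene`` against each score over the gated cell subset."""
    if not ann.matches(norm):
        raise ValueError("annotation does not cover the normalized matrix")
    if not scores:
        raise ValueError("no scores supplied")
    expr = pd.Series(norm.gene_row(gene), index=norm.cells)
    cells = gated_cells(ann, scores, groups, score_gate)
    if len(cells) < 3:
        raise ValueError(
            f"only {len(cells)} cell(s) pass the gate; need >= 3")
    gate_desc = (f"groups={{{','.join(sorted(set(groups)))}}}, "
                 f"all scores > {score_gate}")
    x = expr.loc[cells].to_numpy()
    out = []
    for sc in scores:
        y = sc.series().loc[cells].to_numpy()
        r, p = scipy.stats.pearsonr(x, y)
        out.append(CorrelationResult(
            gene=gene, score_name=sc.name, r=float(r), p=float(p),
            n_cells=len(cells), gate=gate_desc))
    return out
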