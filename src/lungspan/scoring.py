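"""Functional-module (cell) scores with abundance-binned random controls.

For a gene set Gj and cell i the score is

    SC_j(i) = mean(Er(Gj, i)) - mean(Er(Gj_cont, i))

where Er is the log-normalized expression value and Gj_cont is a control
gene pool: every matrix gene is assigned to one of ``n_bins`` equally sized
mean-expression bins, and for each target gene ``controls_per_gene`` genes
are drawn from the target's bin (excluding Gj members). The pooled control
draws (with multiplicity) make the control average's expression
distribution comparable to the gene set's, so the score measures relative
rather than absolute expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellAnnotation, GeneSet, NormalizedMatrix
from .noise import equal_size_bins

log = logging.getLogger("lungspan")

__all__ = ["ControlGeneAssignment", "ScoreResult", "assign_control_genes",
           "module_score", "score_gene_sets"]


@dataclass
class ControlGeneAssignment:
    """Control draw per target gene (gene -> list of control genes)."""

    gene_set: str
    n_bins: int
    controls_per_gene: int
    seed: int
    controls: dict[str, list[str]]

    def pooled(self) -> list[str]:
        out: list[str] = []
        for genes in self.controls.values():
            out.extend(genes)
        return out


@dataclass
class ScoreResult:
    """Per-cell signature score with its two averaged components."""

    name: str
    cells: list[str]
    score: np.ndarray
    set_mean: np.ndarray
    control_mean: np.ndarray

    def series(self) -> pd.Series:
        return pd.Series(self.score, index=self.cells, name=self.name)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": self.cells,
            "score_name": self.name,
            "score": self.score,
            "set_mean": self.set_mean,
            "control_mean": self.control_mean,
        })


def assign_control_genes(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    n_bins: int = 25,
    controls_per_gene: int = 100,
    seed: int = 0,
) -> ControlGeneAssignment:
    """Sample abundance-matched control genes for every target gene.

    Controls are drawn uniformly without replacement from the target's
    mean-expression bin once Gj members are excluded; with replacement only
    when the bin holds fewer candidates than ``controls_per_gene``. A bin
    left with no candidates falls back to the nearest non-empty bin (logged).
    """
    members = gene_set.intersect(norm.genes)
    if not members:
        raise ValueError(
            f"gene set {gene_set.name!r} is disjoint from the matrix")
    rng = np.random.default_rng(seed)
    mean = norm.values.mean(axis=1)
    order = np.argsort(mean, kind="stable")
    bins = equal_size_bins(order, n_bins)
    bin_of = np.empty(norm.n_genes, dtype=int)
    for b, idxs in enumerate(bins):
        bin_of[idxs] = b
    exclude = set(gene_set.genes)
    candidates = [
        np.array([i for i in idxs if norm.genes[i] not in exclude], dtype=int)
        for idxs in bins
    ]

    controls: dict[str, list[str]] = {}
    gene_index = {g: i for i, g in enumerate(norm.genes)}
    for g in members:
        b = bin_of[gene_index[g]]
        cand = candidates[b]
        if cand.size == 0:
            for off in range(1, n_bins):
                for bb in (b - off, b + off):
                    if 0 <= bb < n_bins and candidates[bb].size:
                        cand = candidates[bb]
                        break
                if cand.size:
                    break
            log.warning(
                "bin %d empty after excluding %s members; controls for %r "
                "drawn from nearest non-empty bin", b, gene_set.name, g)
        if cand.size == 0:
            raise ValueError("no candidate control genes outside the gene set")
        if cand.size >= controls_per_gene:
            chosen = rng.choice(cand, size=controls_per_gene, replace=False)
        else:
            chosen = rng.choice(cand, size=controls_per_gene, replace=True)
        controls[g] = [norm.genes[i] for i in chosen]
    return ControlGeneAssignment(
        gene_set.name, n_bins, controls_per_gene, seed, controls)


def module_score(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    assignment: ControlGeneAssignment,
) -> ScoreResult:
    """SC_j(i) = mean over Gj minus mean over the pooled control draws."""
    if assignment.gene_set != gene_set.name:
        raise ValueError("assignment was built for a different gene set")
    members = gene_set.intersect(norm.genes)
    if not members:
        raise ValueError("gene set is disjoint from the matrix")
    gene_index = {g: i for i, g in enumerate(norm.genes)}
    set_rows = [gene_index[g] for g in members]
    control_rows = [gene_index[g] for g in assignment.pooled()]
    set_mean = norm.values[set_rows].mean(axis=0)
    control_mean = norm.values[control_rows].mean(axis=0)
    return ScoreResult(
        name=gene_set.name,
        cells=list(norm.cells),
        score=set_mean - control_mean,
        set_mean=set_mean,
        control_mean=control_mean,
    )


def score_gene_sets(
    norm: NormalizedMatrix,
    gene_sets: list[GeneSet],
    n_bins: int = 25,
    controls_per_gene: int = 100,
    seed: int = 0,
) -> list[ScoreResult]:
    """Convenience: assign controls and score each set (seed offset per set)."""
    out = []
    for k, gs in enumerate(gene_sets):
        assignment = assign_control_genes(
            norm, gs, n_bins=n_bins, controls_per_gene=controls_per_gene,
            seed=seed + k)
        out.append(module_score(norm, gs, assignment))
    return out
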