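"""Per-gene two-group differential expression with BH FDR.

Genes are pre-filtered to those detected in at least ``min_pct`` of cells in
one of the two groups and with |log2 fold change| at least
``logfc_threshold``; the surviving genes get a Welch two-sample t-test on
log-normalized values and Benjamini-Hochberg adjustment over the tested
genes only. The fold change de-logs the group means first:
``log2((mean(expm1 x) + pseudocount) / (mean(expm1 y) + pseudocount))``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import CellAnnotation, GeneSet, NormalizedMatrix

log = logging.getLogger("lungspan")

__all__ = ["deg_t_test", "bh_adjust", "overlap_disease_genes"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_t_test(
    norm: NormalizedMatrix,
    ann: CellAnnotation,
    group_a: str,
    group_b: str,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test DEG table for group_a vs group_b.

    Columns: gene, log2FC (A over B), p, p_adj, pct_a, pct_b. An empty
    table (no gene passes the pre-filter) is returned, not raised.
    """
    if not ann.matches(norm):
        raise ValueError("annotation does not cover the normalized matrix")
    grp = ann.table["group"].astype(str).to_numpy()
    mask_a = grp == group_a
    mask_b = grp == group_b
    for name, mask in ((group_a, mask_a), (group_b, mask_b)):
        if mask.sum() < 3:
            raise ValueError(f"group {name!r} has fewer than 3 cells")
    Xa = norm.values[:, mask_a]
    Xb = norm.values[:, mask_b]
    pct_a = (Xa > 0).mean(axis=1)
    pct_b = (Xb > 0).mean(axis=1)
    mean_a = np.expm1(Xa).mean(axis=1)
    mean_b = np.expm1(Xb).mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    tested = ((np.maximum(pct_a, pct_b) >= min_pct)
              & (np.abs(log2fc) >= logfc_threshold))
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(
            columns=["gene", "log2FC", "p", "p_adj", "pct_a", "pct_b"])
    res = scipy.stats.ttest_ind(Xa[idx], Xb[idx], axis=1, equal_var=False)
    p = np.asarray(res.pvalue)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both genes
    table = pd.DataFrame({
        "gene": [norm.genes[i] for i in idx],
        "log2FC": log2fc[idx],
        "p": p,
        "p_adj": bh_adjust(p),
        "pct_a": pct_a[idx],
        "pct_b": pct_b[idx],
    })
    log.info("DEG %s vs %s: %d genes tested", group_a, group_b, len(table))
    return table.reset_index(drop=True)


def overlap_disease_genes(
    deg: pd.DataFrame,
    disease_lists: dict[str, GeneSet],
    p_cut: float = 0.05,
    lfc_cut: float = 0.25,
) -> pd.DataFrame:
    """Intersect up-regulated significant DEGs with disease gene lists.

    Selection rule: p < ``p_cut`` and log2FC > ``lfc_cut`` (one-sided on the
    fold change, matching 'average log2 fold change > 0.25').
    """
    if not disease_lists:
        raise ValueError("no disease lists supplied")
    if deg.empty:
        selected: set[str] = set()
    else:
        hit = (deg["p"] < p_cut) & (deg["log2FC"] > lfc_cut)
        selected = set(deg.loc[hit, "gene"])
    rows = []
    for name, gs in disease_lists.items():
        overlap = sorted(selected & set(gs.genes))
        rows.append((name, len(overlap), ",".join(overlap)))
    return pd.DataFrame(rows, columns=["disease_list", "n_overlap", "genes"])
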